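"""Instrument resolution model and charge-vs-mass expectation.

The single-ion charge uncertainty dominates the mass error and scales with
(trapping time)^-1/2, anchored at 1 e RMSD for 100 ms trapping.  Expected
charge follows a surface-area-like (mass^(2/3)) law under the charge-residue
mechanism, anchored at 150 e for a 3.7 MDa compact particle; per-species
shape factors absorb deviations for extended structures.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .capsid import CapsidMassDistribution

__all__ = [
    "InstrumentConfig",
    "ChargeModel",
    "PeakShape",
    "charge_sigma",
    "mass_sigma",
    "mean_charge",
    "expected_peak_shape",
]

REFERENCE_TRAP_TIME_MS = 100.0


@dataclass(frozen=True)
class InstrumentConfig:
    """CDMS acquisition parameters.

    ``sigma_z_ref`` is the charge RMSD (e) at the 100 ms reference trapping
    time; ``rel_sigma_mz`` the relative m/z RMSD; ``bin_width`` the mass
    histogram bin width in Da.  ``multiple_ion_rate`` / ``short_trap_rate``
    are the probabilities that an event is flagged (and later discarded) as
    a multi-ion trap or an incomplete trapping period.
    """

    trap_time: float = 100.0  # ms
    sigma_z_ref: float = 1.0  # e at 100 ms
    rel_sigma_mz: float = 0.001
    bin_width: float = 20_000.0  # Da
    multiple_ion_rate: float = 0.05
    short_trap_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.trap_time <= 0:
            raise ValueError(f"trap_time must be positive, got {self.trap_time}")
        if self.sigma_z_ref < 0 or self.rel_sigma_mz < 0:
            raise ValueError("noise parameters must be nonnegative")
        if self.bin_width <= 0:
            raise ValueError("bin_width must be positive")
        for name in ("multiple_ion_rate", "short_trap_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")


@dataclass(frozen=True)
class ChargeModel:
    """Mean-charge law z(m) = shape_factor * z_ref * (m / m_ref)^exponent."""

    z_ref: float = 150.0  # e
    m_ref: float = 3.7e6  # Da
    exponent: float = 2.0 / 3.0
    shape_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.z_ref <= 0 or self.m_ref <= 0:
            raise ValueError("z_ref and m_ref must be positive")
        if self.shape_factor < 1:
            raise ValueError(f"shape_factor must be >= 1, got {self.shape_factor}")


def charge_sigma(cfg: InstrumentConfig) -> float:
    """Charge RMSD (e) at the configured trapping time: sigma_ref * (t/100ms)^-1/2."""
    return cfg.sigma_z_ref * math.sqrt(REFERENCE_TRAP_TIME_MS / cfg.trap_time)


def mass_sigma(mass, charge, cfg: InstrumentConfig):
    """Single-ion mass RMSD (Da): quadrature of (m/z)*sigma_z and m*rel_sigma_mz."""
    mass = np.asarray(mass, dtype=float)
    charge = np.asarray(charge, dtype=float)
    if np.any(mass <= 0) or np.any(charge <= 0):
        raise ValueError("mass and charge must be positive")
    sz = charge_sigma(cfg)
    out = np.sqrt((mass / charge * sz) ** 2 + (mass * cfg.rel_sigma_mz) ** 2)
    return float(out) if out.ndim == 0 else out


def mean_charge(mass, charge_model: ChargeModel, shape_factor: float | None = None):
    """Expected charge (e) for a particle of the given mass."""
    mass = np.asarray(mass, dtype=float)
    if np.any(mass <= 0):
        raise ValueError("mass must be positive")
    factor = charge_model.shape_factor if shape_factor is None else shape_factor
    out = factor * charge_model.z_ref * (mass / charge_model.m_ref) ** charge_model.exponent
    return float(out) if out.ndim == 0 else out


class PeakShape(NamedTuple):
    """Normalized density on a uniform mass grid."""

    grid: np.ndarray  # Da
    density: np.ndarray  # 1/Da

    @property
    def mean(self) -> float:
        return float(np.trapezoid(self.grid * self.density, self.grid))

    @property
    def sd(self) -> float:
        var = float(np.trapezoid((self.grid - self.mean) ** 2 * self.density, self.grid))
        return math.sqrt(max(var, 0.0))


def expected_peak_shape(
    pmf: CapsidMassDistribution,
    dna_mass: float,
    cfg: InstrumentConfig,
    charge_model: ChargeModel,
    grid: np.ndarray | None = None,
    n_points: int = 4001,
) -> PeakShape:
    """Predicted mass-peak density: capsid heterogeneity convolved with resolution.

    The capsid pmf is shifted by ``dna_mass`` and each support point is
    broadened by a Gaussian of width :func:`mass_sigma` evaluated at that
    point's mass and model charge.  The returned density is normalized on
    the grid, which must cover the support plus 5 total sigma on both sides.
    """
    if dna_mass < 0:
        raise ValueError("dna_mass must be >= 0")
    masses = pmf.masses + dna_mass
    charges = mean_charge(masses, charge_model)
    sigmas = mass_sigma(masses, charges, cfg)
    sig_tot = math.sqrt(pmf.sd**2 + float(np.dot(pmf.probs, sigmas**2)))
    lo = masses.min() - 5.0 * sig_tot
    hi = masses.max() + 5.0 * sig_tot
    if grid is None:
        grid = np.linspace(lo, hi, n_points)
    else:
        grid = np.asarray(grid, dtype=float)
        if grid[0] > masses.min() - 4.0 * sig_tot or grid[-1] < masses.max() + 4.0 * sig_tot:
            raise ValueError(
                "grid too narrow: must cover the shifted pmf support +/- ~5 total sigma "
                f"(need about [{lo:.0f}, {hi:.0f}] Da)"
            )
    # sum of Gaussians, vectorized over (support, grid)
    zscores = (grid[None, :] - masses[:, None]) / sigmas[:, None]
    dens = np.exp(-0.5 * zscores**2) / (sigmas[:, None] * math.sqrt(2 * math.pi))
    density = pmf.probs @ dens
    norm = np.trapezoid(density, grid)
    if norm <= 0:
        raise ValueError("grid does not capture any probability mass")
    return PeakShape(grid, density / norm)
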