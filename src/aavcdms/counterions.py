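"""Counterion mass-balance model for measured full-minus-empty mass differences.

An empty capsid with ``i`` internal basic sites carries ``i`` anions of mean
mass ``m_minus``.  A full capsid carries the genome (``j`` nucleotides of
mean ionized mass ``m_N``) plus one cation of mean mass ``m_plus`` per
nucleotide charge not neutralized by the basic sites.  The full-minus-empty
difference is then linear in the genome sequence mass ``j * m_N`` with slope
``1 + m_plus_eff / m_N`` and intercept ``-i * (m_plus_eff + m_minus)``, so
fitting measured differences against sequence masses yields the effective
cation mass (slope) and the basic-site count (intercept).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

from .constants import ACETATE_MASS, AMMONIUM_MASS, DEFAULT_PER_BASE_MASS

__all__ = [
    "CounterionParams",
    "CounterionFit",
    "empty_particle_mass",
    "full_particle_mass",
    "predicted_mass_difference",
    "expected_slope",
    "fit_counterion_model",
    "interpret_fit",
    "read_points_table",
]


@dataclass(frozen=True)
class CounterionParams:
    """Parameters of the mass-balance model.

    M: bare capsid mass (Da); i: internal basic sites; j: nucleotide count;
    m_N: mean ionized nucleotide mass (Da); m_plus/m_minus: mean cation and
    anion masses (Da); valence: cation valence (1 or 2).
    """

    M: float
    i: float
    j: float
    m_N: float = DEFAULT_PER_BASE_MASS
    m_plus: float = AMMONIUM_MASS
    m_minus: float = ACETATE_MASS
    valence: int = 1

    def __post_init__(self) -> None:
        if min(self.M, self.m_N, self.m_plus, self.m_minus) < 0:
            raise ValueError("masses must be nonnegative")
        if self.i < 0 or self.j < 0:
            raise ValueError("i and j must be nonnegative")
        if self.valence not in (1, 2):
            raise ValueError(f"valence must be 1 or 2, got {self.valence}")
        if self.m_N <= 0:
            raise ValueError("m_N must be positive")

    @property
    def m_plus_eff(self) -> float:
        """Cation mass per neutralized nucleotide charge, Da."""
        return self.m_plus / self.valence


def empty_particle_mass(p: CounterionParams) -> float:
    """Empty capsid with internal counteranions: M + i * m_minus (Da)."""
    return p.M + p.i * p.m_minus


def full_particle_mass(p: CounterionParams) -> float:
    """Full capsid: M + j * m_N + (j - i) * m_plus_eff (Da)."""
    return p.M + p.j * p.m_N + (p.j - p.i) * p.m_plus_eff


def predicted_mass_difference(p: CounterionParams) -> float:
    """Full-minus-empty mass difference (Da).

    Computed as ``(1 + m_plus_eff/m_N) * (j * m_N) - i * (m_plus_eff + m_minus)``;
    algebraically identical to ``full_particle_mass - empty_particle_mass``.
    """
    return (1.0 + p.m_plus_eff / p.m_N) * (p.j * p.m_N) - p.i * (p.m_plus_eff + p.m_minus)


def expected_slope(m_plus: float, valence: int = 1, m_N: float = DEFAULT_PER_BASE_MASS) -> float:
    """Predicted slope of mass difference vs sequence mass: 1 + (m_plus/valence)/m_N."""
    if m_N <= 0:
        raise ValueError("m_N must be positive")
    if valence not in (1, 2):
        raise ValueError(f"valence must be 1 or 2, got {valence}")
    return 1.0 + (m_plus / valence) / m_N


@dataclass(frozen=True)
class CounterionFit:
    """OLS fit of measured mass difference on genome sequence mass.

    The derived fields (``m_plus_eff``, ``i_total``, ``i_per_protein``) are
    filled by :func:`interpret_fit`; ``negative_sites`` flags a positive
    intercept, which implies an unphysical negative basic-site count.
    """

    slope: float
    intercept: float  # Da
    r_squared: float
    n_points: int
    m_plus_eff: float | None = None
    i_total: float | None = None
    i_per_protein: float | None = None
    negative_sites: bool = False


def fit_counterion_model(points) -> CounterionFit:
    """Ordinary least squares of measured difference (Da) on sequence mass (Da).

    ``points`` is an iterable of (sequence_mass, measured_difference) pairs
    or a two-column array.
    """
    arr = np.asarray(list(points) if not isinstance(points, np.ndarray) else points, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("points must be (sequence_mass, measured_difference) pairs")
    x, y = arr[:, 0], arr[:, 1]
    if len(x) < 2:
        raise ValueError("at least two points are required to fit a line")
    if np.ptp(x) == 0:
        raise ValueError("sequence masses are all identical; the slope is undefined")
    res = stats.linregress(x, y)
    return CounterionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_points=len(x),
    )


def interpret_fit(
    fit: CounterionFit,
    m_N: float = DEFAULT_PER_BASE_MASS,
    m_plus_assumed: float = AMMONIUM_MASS,
    m_minus_assumed: float = ACETATE_MASS,
    n_proteins: int = 60,
) -> CounterionFit:
    """Physical reading of a fit: effective cation mass and basic-site count.

    ``m_plus_eff = (slope - 1) * m_N``; ``i_total = -intercept / (m_plus_assumed
    + m_minus_assumed)`` under caller-supplied counterion identities (default
    ammonium/acetate, the electrospray buffer).  A positive intercept yields a
    negative ``i_total`` which is returned with ``negative_sites=True`` rather
    than raising.
    """
    if m_N <= 0:
        raise ValueError("m_N must be positive")
    if m_plus_assumed + m_minus_assumed <= 0:
        raise ValueError("assumed counterion masses must sum to a positive value")
    if n_proteins < 1:
        raise ValueError("n_proteins must be >= 1")
    m_plus_eff = (fit.slope - 1.0) * m_N
    i_total = -fit.intercept / (m_plus_assumed + m_minus_assumed)
    return replace(
        fit,
        m_plus_eff=m_plus_eff,
        i_total=i_total,
        i_per_protein=i_total / n_proteins,
        negative_sites=i_total < 0,
    )


def read_points_table(path) -> list[tuple[float, float]]:
    """Read (name, sequence_mass_da, measured_difference_da) delimited text."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    needed = {"sequence_mass_da", "measured_difference_da"}
    if not needed <= set(df.columns):
        raise ValueError(f"points table needs columns {sorted(needed)}")
    return list(zip(df["sequence_mass_da"].astype(float), df["measured_difference_da"].astype(float)))
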