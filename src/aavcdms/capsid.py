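"""Capsid mass model: multinomial VP1/VP2/VP3 stoichiometry.

Each capsid contains a fixed number of subunits drawn (independently, per
the stochastic-assembly hypothesis) from the three VP species, so per-capsid
composition follows a multinomial distribution and capsid mass is the
corresponding weighted sum of subunit masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import multinomial

from .constants import AAV8_VP_MASSES, AAV8_VP_RATIO, CAPSID_N_SUBUNITS

__all__ = [
    "VPStoichiometry",
    "CapsidMassDistribution",
    "mean_capsid_mass",
    "capsid_mass_pmf",
    "capsid_mass_moments",
    "sample_capsid_masses",
    "AAV8_DEFAULT",
]

MAX_COMPOSITIONS = 10_000


@dataclass(frozen=True)
class VPStoichiometry:
    """Subunit masses, mixing ratio and subunit count of a capsid.

    Parameters
    ----------
    vp_masses:
        Sequence masses of VP1, VP2, VP3 in Da.
    ratio:
        Nonnegative mixing weights; normalized internally to probabilities.
    n_subunits:
        Total number of capsid proteins per particle.
    """

    vp_masses: tuple[float, float, float]
    ratio: tuple[float, float, float]
    n_subunits: int = CAPSID_N_SUBUNITS

    def __post_init__(self) -> None:
        masses = tuple(float(m) for m in self.vp_masses)
        ratio = tuple(float(r) for r in self.ratio)
        if len(masses) != 3 or len(ratio) != 3:
            raise ValueError("vp_masses and ratio must each have three entries")
        if not all(math.isfinite(m) and m > 0 for m in masses):
            raise ValueError(f"vp_masses must be finite and positive, got {masses}")
        if not all(math.isfinite(r) and r >= 0 for r in ratio):
            raise ValueError(f"ratio weights must be finite and nonnegative, got {ratio}")
        if sum(ratio) <= 0:
            raise ValueError("ratio weights must not all be zero")
        if int(self.n_subunits) != self.n_subunits or self.n_subunits < 1:
            raise ValueError(f"n_subunits must be a positive integer, got {self.n_subunits}")
        object.__setattr__(self, "vp_masses", masses)
        object.__setattr__(self, "ratio", ratio)
        object.__setattr__(self, "n_subunits", int(self.n_subunits))

    @property
    def probs(self) -> np.ndarray:
        """Normalized composition probabilities (p1, p2, p3)."""
        r = np.asarray(self.ratio, dtype=float)
        return r / r.sum()


AAV8_DEFAULT = VPStoichiometry(AAV8_VP_MASSES, AAV8_VP_RATIO, CAPSID_N_SUBUNITS)


@dataclass(frozen=True)
class CapsidMassDistribution:
    """Exact capsid-mass pmf over all subunit compositions.

    ``compositions[k]`` holds (n1, n2, n3); equal-mass compositions are kept
    distinct (mass collisions are accidental; merging, if any, happens at
    histogram time).
    """

    compositions: np.ndarray  # (K, 3) int
    masses: np.ndarray  # (K,) Da
    probs: np.ndarray  # (K,)
    mean: float = field(init=False)
    sd: float = field(init=False)

    def __post_init__(self) -> None:
        mean = float(np.dot(self.probs, self.masses))
        var = float(np.dot(self.probs, (self.masses - mean) ** 2))
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "sd", math.sqrt(max(var, 0.0)))

    def __len__(self) -> int:
        return len(self.masses)


def mean_capsid_mass(stoich: VPStoichiometry) -> float:
    """Expected capsid mass in Da: ``n_subunits * sum_i p_i m_i``."""
    return stoich.n_subunits * float(np.dot(stoich.probs, stoich.vp_masses))


def capsid_mass_moments(stoich: VPStoichiometry) -> tuple[float, float]:
    """Closed-form (mean, sd) in Da of the multinomial capsid-mass model."""
    p = stoich.probs
    m = np.asarray(stoich.vp_masses)
    mu1 = float(np.dot(p, m))
    var1 = float(np.dot(p, m * m)) - mu1 * mu1
    n = stoich.n_subunits
    return n * mu1, math.sqrt(max(n * var1, 0.0))


def capsid_mass_pmf(
    stoich: VPStoichiometry, max_compositions: int = MAX_COMPOSITIONS
) -> CapsidMassDistribution:
    """Exact enumeration of the capsid-mass pmf.

    Enumerates every composition (n1, n2, n3) with ``n1+n2+n3 = n_subunits``
    and attaches its multinomial probability.  Guarded against combinatorial
    blow-up; for large subunit counts use :func:`capsid_mass_moments` (or the
    normal approximation in :mod:`aavcdms.instrument`).
    """
    n = stoich.n_subunits
    n_comp = (n + 1) * (n + 2) // 2
    if n_comp > max_compositions:
        raise ValueError(
            f"{n_comp} compositions exceed the enumeration guard "
            f"({max_compositions}); use capsid_mass_moments / a moment "
            "approximation instead"
        )
    n1, n2 = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    keep = (n1 + n2) <= n
    comps = np.column_stack([n1[keep], n2[keep], (n - n1 - n2)[keep]])
    probs = multinomial(n, stoich.probs).pmf(comps)
    masses = comps @ np.asarray(stoich.vp_masses)
    return CapsidMassDistribution(comps, masses, probs)


def sample_capsid_masses(
    stoich: VPStoichiometry,
    size: int,
    rng: np.random.Generator,
    order: int = 1,
) -> np.ndarray:
    """Monte-Carlo capsid (or multimer) protein masses in Da.

    ``order`` > 1 samples a multimer of ``order`` independent capsids, i.e.
    a multinomial over ``order * n_subunits`` subunits.
    """
    if size < 0:
        raise ValueError("size must be nonnegative")
    if order < 1:
        raise ValueError("order must be >= 1")
    counts = rng.multinomial(order * stoich.n_subunits, stoich.probs, size=size)
    return counts @ np.asarray(stoich.vp_masses)
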