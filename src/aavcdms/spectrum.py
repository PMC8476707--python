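"""Spectrum quantitation: binning, mixture fitting, packaging-state fractions.

Analysis operates on accepted (unflagged) single-ion events.  Window-based
classification is the primary quantitation path; 1-D Gaussian-mixture EM
refines component means/widths and carries each component's mean observed
charge so charge-vs-mass structure is assertable on simulated data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .instrument import InstrumentConfig
from .simulate import events_to_arrays

__all__ = [
    "MassSpectrum",
    "ComponentFit",
    "ComponentTable",
    "FitConvergenceError",
    "bin_events",
    "fit_components",
    "classify_packaging",
    "genome_mass_difference",
]

PACKAGING_CLASSES = ("empty", "partial", "full_GOI", "overfull", "multimer")


@dataclass(frozen=True)
class MassSpectrum:
    """Histogram of accepted ion masses on uniform bins anchored at 0 Da."""

    bin_edges: np.ndarray  # Da, length n_bins + 1
    counts: np.ndarray  # int, length n_bins
    n_accepted: int
    n_discarded: int

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def mode_mass(self) -> float:
        """Center of the most populated bin, Da."""
        return float(self.bin_centers[int(np.argmax(self.counts))])

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write(f"# n_accepted={self.n_accepted} n_discarded={self.n_discarded}\n")
            fh.write("bin_center_Da\tcount\n")
            for c, n in zip(self.bin_centers, self.counts):
                fh.write(f"{c:.1f}\t{int(n)}\n")


def bin_events(events, cfg: InstrumentConfig) -> MassSpectrum:
    """Histogram unflagged event masses on half-open bins [left, right).

    Bin edges are integer multiples of ``cfg.bin_width`` (left edge anchored
    at 0 Da), so an event exactly on an edge lands in the bin whose left
    edge it equals.  An empty accepted set yields a valid empty spectrum.
    """
    cols = events_to_arrays(events)
    flagged = cols["multiple_ion"] | cols["short_trap"]
    masses = cols["mass"][~flagged]
    n_discarded = int(flagged.sum())
    bw = cfg.bin_width
    if masses.size == 0:
        return MassSpectrum(np.array([0.0, bw]), np.zeros(1, dtype=int), 0, n_discarded)
    idx = np.floor(masses / bw).astype(np.int64)
    kmin, kmax = int(idx.min()), int(idx.max())
    counts = np.bincount(idx - kmin, minlength=kmax - kmin + 1)
    edges = np.arange(kmin, kmax + 2) * bw
    return MassSpectrum(edges, counts, int(masses.size), n_discarded)


@dataclass(frozen=True)
class ComponentFit:
    label: str
    mean: float  # Da
    sd: float  # Da
    fraction: float  # of accepted ions
    mean_charge: float  # e, over hard-assigned ions


@dataclass(frozen=True)
class ComponentTable:
    components: tuple[ComponentFit, ...]
    n_accepted: int
    log_likelihood: float
    n_iter: int

    def __iter__(self):
        return iter(self.components)

    def __getitem__(self, i):
        return self.components[i]

    def write(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("label\tmean_Da\tsd_Da\tfraction\tmean_charge_e\n")
            for c in self.components:
                fh.write(
                    f"{c.label}\t{c.mean:.2f}\t{c.sd:.2f}\t{c.fraction:.6f}\t{c.mean_charge:.3f}\n"
                )


class FitConvergenceError(RuntimeError):
    """EM failed to converge; ``last_iterate`` holds the final ComponentTable."""

    def __init__(self, message: str, last_iterate: ComponentTable):
        super().__init__(message)
        self.last_iterate = last_iterate


def fit_components(
    events,
    k: int,
    init_means,
    labels: list[str] | None = None,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> ComponentTable:
    """1-D Gaussian-mixture EM over accepted-event masses.

    Initialized at ``init_means`` with a common data-derived width and equal
    weights; terminates when the relative log-likelihood change falls below
    ``tol``.  Each component's mean observed charge is computed over its
    hard-assigned (argmax-responsibility) ions.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    init_means = np.asarray(init_means, dtype=float)
    if init_means.shape != (k,):
        raise ValueError(f"init_means must have length k={k}")
    cols = events_to_arrays(events)
    keep = ~(cols["multiple_ion"] | cols["short_trap"])
    x = cols["mass"][keep]
    z = cols["z"][keep]
    if x.size < 10 * k:
        raise ValueError(f"need at least {10 * k} accepted events to fit {k} components, have {x.size}")

    means = init_means.copy()
    sd0 = max(float(np.std(x)) / max(k, 1), 1e-3)
    sds = np.full(k, sd0)
    weights = np.full(k, 1.0 / k)
    sd_floor = max(1e-9 * float(np.mean(np.abs(x))), 1e-6)

    prev_ll = -np.inf
    converged = False
    for it in range(1, max_iter + 1):
        logp = (
            -0.5 * ((x[None, :] - means[:, None]) / sds[:, None]) ** 2
            - np.log(sds[:, None] * math.sqrt(2 * math.pi))
            + np.log(weights[:, None])
        )
        m = logp.max(axis=0)
        lse = m + np.log(np.exp(logp - m).sum(axis=0))
        ll = float(lse.sum())
        resp = np.exp(logp - lse)
        nk = resp.sum(axis=1)
        weights = nk / x.size
        means = (resp @ x) / nk
        sds = np.sqrt(np.maximum((resp @ x**2) / nk - means**2, sd_floor**2))
        if abs(ll - prev_ll) <= tol * (1.0 + abs(ll)):
            converged = True
            break
        prev_ll = ll

    assign = np.argmax(resp, axis=0)
    comps = []
    names = labels if labels is not None else [f"c{i + 1}" for i in range(k)]
    for i in range(k):
        sel = assign == i
        zc = float(np.mean(z[sel])) if sel.any() else float("nan")
        comps.append(ComponentFit(names[i], float(means[i]), float(sds[i]), float(weights[i]), zc))
    table = ComponentTable(tuple(comps), int(x.size), ll, it)
    if not converged:
        raise FitConvergenceError(f"EM did not converge in {max_iter} iterations", table)
    return table


def classify_packaging(
    events,
    empty_mass: float,
    goi_mass: float,
    capacity_mass: float,
    window_sd: float,
    n_sd: float = 3.0,
    multimer_threshold: float | None = None,
) -> dict[str, float]:
    """Window-based packaging-state fractions over accepted events.

    Empty and full windows are +/- ``n_sd * window_sd`` around ``empty_mass``
    and ``empty_mass + goi_mass``; masses between the windows are partial,
    above the full window up to ``multimer_threshold`` overfull/headful, and
    beyond that multimer.  Ties at window boundaries go to the lower-mass
    state.  ``multimer_threshold`` defaults to the midpoint between the
    capacity mass and the empty-dimer mass.
    """
    if goi_mass <= 0:
        raise ValueError("goi_mass must be positive")
    if window_sd <= 0 or n_sd <= 0:
        raise ValueError("window_sd and n_sd must be positive")
    full_mass = empty_mass + goi_mass
    if not full_mass <= capacity_mass * 1.05:
        raise ValueError("inconsistent thresholds: empty_mass + goi_mass far exceeds capacity_mass")
    half = n_sd * window_sd
    empty_hi = empty_mass + half
    full_lo, full_hi = full_mass - half, full_mass + half
    if empty_hi >= full_lo:
        raise ValueError(
            "empty and full windows overlap; use a narrower window_sd or smaller n_sd"
        )
    if multimer_threshold is None:
        multimer_threshold = 0.5 * (capacity_mass + 2.0 * empty_mass)
    if multimer_threshold <= full_hi:
        raise ValueError("multimer_threshold must lie above the full window")

    cols = events_to_arrays(events)
    keep = ~(cols["multiple_ion"] | cols["short_trap"])
    masses = cols["mass"][keep]
    fractions = dict.fromkeys(PACKAGING_CLASSES, 0.0)
    if masses.size == 0:
        return fractions
    n = masses.size
    fractions["empty"] = float(np.sum(masses <= empty_hi)) / n
    fractions["partial"] = float(np.sum((masses > empty_hi) & (masses <= full_lo))) / n
    fractions["full_GOI"] = float(np.sum((masses > full_lo) & (masses <= full_hi))) / n
    fractions["overfull"] = float(np.sum((masses > full_hi) & (masses <= multimer_threshold))) / n
    fractions["multimer"] = float(np.sum(masses > multimer_threshold)) / n
    return fractions


def genome_mass_difference(full_mean: float, empty_mean: float) -> float:
    """Deduced genome mass (Da): measured full mean minus empty mean.

    A negative difference is returned as-is with a warning.
    """
    diff = full_mean - empty_mean
    if diff < 0:
        warnings.warn(
            f"full mean ({full_mean:.1f} Da) below empty mean ({empty_mean:.1f} Da); "
            "negative genome mass",
            stacklevel=2,
        )
    return diff
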