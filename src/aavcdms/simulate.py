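"""Forward simulator of single-ion CDMS events from a particle mixture.

Each trapped ion gets a true mass (multinomial capsid + packaged DNA +
co-packaged fragment), a charge-residue-style true charge, and trapping-
time-dependent Gaussian measurement noise on charge and m/z.  Events may be
flagged as multi-ion traps or short trapping periods; flagged events are
excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .capsid import VPStoichiometry, sample_capsid_masses
from .constants import AAV8_CAPACITY_DA
from .genome import PackagingState
from .instrument import ChargeModel, InstrumentConfig, charge_sigma, mean_charge

__all__ = [
    "MixtureComponent",
    "IonEvent",
    "simulate_ion_events",
    "apply_incubation",
    "write_events",
    "read_events",
    "events_to_arrays",
    "accepted_masses",
]

DEFAULT_DNA_MASS_SCALE = 1.041
"""Default counterion inflation applied to packaged GOI DNA mass."""


@dataclass(frozen=True)
class MixtureComponent:
    """One particle species in a simulated mixture.

    ``extra_dna`` = (mean, sd) in Da of a Gaussian (truncated at 0)
    co-packaged heterogeneous-fragment mass.  ``partial_fraction_range``
    bounds the uniform fraction of the GOI mass drawn for ``partial``
    states.  ``multimer_order`` >= 2 makes the species an n-mer of capsids.
    """

    label: str
    packaging_state: PackagingState
    capsid: VPStoichiometry
    weight: float
    charge_shape_factor: float = 1.0
    extra_dna: tuple[float, float] = (0.0, 0.0)
    multimer_order: int = 1
    partial_fraction_range: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise ValueError("weight must be >= 0")
        if self.charge_shape_factor < 1:
            raise ValueError("charge_shape_factor must be >= 1")
        if self.extra_dna[0] < 0 or self.extra_dna[1] < 0:
            raise ValueError("extra_dna mean and sd must be >= 0")
        if self.multimer_order < 1:
            raise ValueError("multimer_order must be >= 1")
        lo, hi = self.partial_fraction_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("partial_fraction_range must satisfy 0 <= lo <= hi <= 1")


@dataclass(frozen=True, slots=True)
class IonEvent:
    """One trapped ion: m/z (Th), charge (e, real-valued after noise), mass (Da)."""

    mz: float
    z: float
    mass: float
    multiple_ion: bool = False
    short_trap: bool = False

    @property
    def flagged(self) -> bool:
        return self.multiple_ion or self.short_trap


def _draw_goi_dna(
    comp: MixtureComponent,
    n: int,
    rng: np.random.Generator,
    capsid_masses: np.ndarray,
    capacity: float,
    capacity_sd: float,
    dna_mass_scale: float,
    dna_mass_offset: float,
) -> np.ndarray:
    """Final (counterion-inflated) packaged-DNA mass per particle, Da."""
    state = comp.packaging_state
    kind = state.kind
    if kind == "empty":
        return np.zeros(n)
    if kind == "headful":
        # packaging proceeds to capacity; the measured total is pinned there,
        # so inflation is already folded into the capacity guide
        target = rng.normal(capacity, capacity_sd, size=n)
        return np.maximum(target - capsid_masses, 0.0)
    if kind in ("full_GOI", "multimer"):
        goi = np.full(n, state.genome_copies * state.dna_mass)
    elif kind == "partial":
        lo, hi = comp.partial_fraction_range
        goi = rng.uniform(lo, hi, size=n) * state.dna_mass
    else:  # pragma: no cover
        raise AssertionError(f"unhandled packaging kind {kind!r}")
    return goi * dna_mass_scale + np.where(goi > 0, dna_mass_offset, 0.0)


def simulate_ion_events(
    mixture: list[MixtureComponent],
    cfg: InstrumentConfig,
    charge_model: ChargeModel,
    n_ions: int,
    seed: int | np.random.SeedSequence,
    dna_mass_scale: float = DEFAULT_DNA_MASS_SCALE,
    dna_mass_offset: float = 0.0,
    capacity: float = AAV8_CAPACITY_DA,
    capacity_sd: float = 80_000.0,
) -> list[IonEvent]:
    """Simulate ``n_ions`` single-ion events; bit-reproducible from ``seed``.

    Packaged GOI mass is scaled by ``dna_mass_scale`` (counterion inflation)
    and, for DNA-carrying particles, shifted by ``dna_mass_offset`` (the
    basic-site intercept term, Da).  Headful species are pinned near
    ``capacity`` with SD ``capacity_sd``.
    """
    if n_ions < 0:
        raise ValueError("n_ions must be >= 0")
    if not mixture:
        raise ValueError("mixture must contain at least one component")
    weights = np.array([c.weight for c in mixture], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("mixture weights must sum to a positive value")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1, got {weights.sum():.6g}")
    if n_ions == 0:
        return []

    rng = np.random.default_rng(seed)
    comp_idx = rng.choice(len(mixture), size=n_ions, p=weights)

    true_mass = np.empty(n_ions)
    shape = np.empty(n_ions)
    for k, comp in enumerate(mixture):
        sel = np.flatnonzero(comp_idx == k)
        if sel.size == 0:
            continue
        capsid_m = sample_capsid_masses(comp.capsid, sel.size, rng, order=comp.multimer_order)
        dna = _draw_goi_dna(
            comp, sel.size, rng, capsid_m, capacity, capacity_sd, dna_mass_scale, dna_mass_offset
        )
        mean_x, sd_x = comp.extra_dna
        extra = np.maximum(rng.normal(mean_x, sd_x, size=sel.size), 0.0) if (mean_x or sd_x) else 0.0
        true_mass[sel] = capsid_m + dna + extra
        shape[sel] = comp.charge_shape_factor

    z_true = mean_charge(true_mass, charge_model, shape_factor=1.0) * shape
    z_obs = z_true + rng.normal(0.0, charge_sigma(cfg), size=n_ions)
    mz_obs = (true_mass / z_true) * (1.0 + rng.normal(0.0, cfg.rel_sigma_mz, size=n_ions))
    mass_obs = mz_obs * z_obs
    multi = rng.random(n_ions) < cfg.multiple_ion_rate
    short = rng.random(n_ions) < cfg.short_trap_rate

    return [
        IonEvent(float(mz_obs[i]), float(z_obs[i]), float(mass_obs[i]), bool(multi[i]), bool(short[i]))
        for i in range(n_ions)
    ]


def apply_incubation(
    mixture: list[MixtureComponent], removal_fraction: float
) -> list[MixtureComponent]:
    """Heat-incubation scenario: remove a fraction of co-packaged fragments.

    Scales every component's extra-DNA mean and sd by (1 - removal_fraction);
    all other fields are unchanged.
    """
    if not 0 <= removal_fraction <= 1:
        raise ValueError(f"removal_fraction must be in [0, 1], got {removal_fraction}")
    keep = 1.0 - removal_fraction
    return [
        replace(c, extra_dna=(c.extra_dna[0] * keep, c.extra_dna[1] * keep)) for c in mixture
    ]


# --- event table I/O (delimited text) ------------------------------------


def events_to_arrays(events) -> dict[str, np.ndarray]:
    """Column arrays (mz, z, mass, multiple_ion, short_trap) from an event list."""
    n = len(events)
    out = {
        "mz": np.empty(n),
        "z": np.empty(n),
        "mass": np.empty(n),
        "multiple_ion": np.empty(n, dtype=bool),
        "short_trap": np.empty(n, dtype=bool),
    }
    for i, e in enumerate(events):
        out["mz"][i] = e.mz
        out["z"][i] = e.z
        out["mass"][i] = e.mass
        out["multiple_ion"][i] = e.multiple_ion
        out["short_trap"][i] = e.short_trap
    return out


def accepted_masses(events) -> np.ndarray:
    """Masses (Da) of unflagged events."""
    return np.array([e.mass for e in events if not e.flagged])


def write_events(events, path: str | Path, seed: int | None = None) -> None:
    """Write events as tab-separated text; the seed is recorded in the header."""
    path = Path(path)
    with path.open("w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        fh.write("mz_Th\tz_e\tmass_Da\tflags\n")
        for e in events:
            flags = "|".join(
                name
                for name, on in (("multiple_ion", e.multiple_ion), ("short_trap", e.short_trap))
                if on
            ) or "-"
            fh.write(f"{e.mz:.6f}\t{e.z:.6f}\t{e.mass:.6f}\t{flags}\n")


def read_events(path: str | Path) -> list[IonEvent]:
    """Read an event table written by :func:`write_events`."""
    events = []
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("mz_Th"):
                continue
            mz_s, z_s, mass_s, flags = line.split("\t")
            events.append(
                IonEvent(
                    float(mz_s),
                    float(z_s),
                    float(mass_s),
                    "multiple_ion" in flags,
                    "short_trap" in flags,
                )
            )
    return events
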