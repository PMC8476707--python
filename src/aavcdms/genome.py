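"""ssDNA genome masses and expected vector (particle) masses.

Genome masses are for the ionized strand (one proton removed per backbone
phosphate) and are always strand-averaged: plus and minus strands are
packaged with equal frequency, so the mass relevant to a particle-mass
distribution is the mean of the two strand masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

from .constants import (
    AAV8_CONSTRUCTS,
    DEFAULT_PER_BASE_MASS,
    DNA_RESIDUE_AVG_MASS,
    PROTON_MASS,
    WATER_MASS,
)

__all__ = [
    "GenomeConstruct",
    "PackagingState",
    "StrandMasses",
    "genome_mass_from_length",
    "genome_mass_from_sequence",
    "expected_vector_mass",
    "read_fasta_constructs",
    "read_construct_table",
    "aav8_construct_table",
]

VALID_BASES = set("ACGTN")
PACKAGING_KINDS = ("empty", "partial", "full_GOI", "headful", "multimer")


class StrandMasses(NamedTuple):
    """Ionized masses (Da) of the sense strand, its reverse complement, and their mean."""

    plus: float
    minus: float
    average: float


@dataclass(frozen=True)
class GenomeConstruct:
    """A named vector genome, specified by length and/or sequence.

    ``n_bases`` includes the ITRs.  ``sequence`` (if present) is the sense
    (+) strand; the minus strand always contributes via the strand average.
    """

    name: str
    n_bases: int
    sequence: str | None = None
    per_base_mass: float = DEFAULT_PER_BASE_MASS

    def __post_init__(self) -> None:
        if self.n_bases < 0:
            raise ValueError(f"n_bases must be >= 0, got {self.n_bases}")
        if self.per_base_mass <= 0:
            raise ValueError("per_base_mass must be positive")
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.n_bases:
                raise ValueError(
                    f"sequence length {len(seq)} != n_bases {self.n_bases} for {self.name!r}"
                )
            _validate_alphabet(seq)
            object.__setattr__(self, "sequence", seq)

    def mass(self) -> float:
        """Strand-averaged ionized genome mass, Da.

        Sequence mode when a sequence is available, otherwise length mode.
        """
        if self.sequence is not None:
            return genome_mass_from_sequence(self.sequence).average
        return genome_mass_from_length(self.n_bases, self.per_base_mass)


@dataclass(frozen=True)
class PackagingState:
    """DNA content of one particle species."""

    kind: str
    dna_mass: float = 0.0
    genome_copies: float = 1.0
    extra_dna_mass: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in PACKAGING_KINDS:
            raise ValueError(f"kind must be one of {PACKAGING_KINDS}, got {self.kind!r}")
        if self.dna_mass < 0 or self.extra_dna_mass < 0:
            raise ValueError("dna_mass and extra_dna_mass must be >= 0")
        if self.genome_copies < 0:
            raise ValueError("genome_copies must be >= 0")
        if self.kind == "empty" and self.dna_mass != 0:
            raise ValueError("an empty state carries no GOI mass (dna_mass must be 0)")


def _validate_alphabet(seq: str) -> None:
    for pos, base in enumerate(seq):
        if base not in VALID_BASES:
            raise ValueError(
                f"invalid nucleotide {base!r} at position {pos} (alphabet ACGTN)"
            )


def genome_mass_from_length(n_bases: int, per_base_mass: float = DEFAULT_PER_BASE_MASS) -> float:
    """Ionized ssDNA mass (Da) from base count: ``n_bases * per_base_mass``.

    Length mode ignores terminal groups (<= 18 Da per strand, far below
    reporting precision).
    """
    if n_bases < 0:
        raise ValueError(f"n_bases must be >= 0, got {n_bases}")
    if per_base_mass <= 0:
        raise ValueError("per_base_mass must be positive")
    return n_bases * per_base_mass


def _strand_mass(seq: str) -> float:
    n_mean = sum(DNA_RESIDUE_AVG_MASS.values()) / 4.0
    total = 0.0
    for base in seq:
        total += n_mean if base == "N" else DNA_RESIDUE_AVG_MASS[base]
    return total - len(seq) * PROTON_MASS + WATER_MASS


def genome_mass_from_sequence(seq: str) -> StrandMasses:
    """Ionized masses of a sense strand, its reverse complement, and their mean.

    Per-residue average masses, one proton removed per phosphate, one water
    per strand terminus.  ``N`` counts as the four-base mean.
    """
    seq = seq.upper()
    _validate_alphabet(seq)
    plus = _strand_mass(seq)
    minus = _strand_mass(str(Seq(seq).reverse_complement()))
    return StrandMasses(plus, minus, (plus + minus) / 2.0)


def expected_vector_mass(empty_mass: float, genome_mass: float, copies: float = 1.0) -> float:
    """Expected particle mass: ``empty_mass + copies * genome_mass`` (Da)."""
    if empty_mass < 0 or genome_mass < 0 or copies < 0:
        raise ValueError("empty_mass, genome_mass and copies must be >= 0")
    return empty_mass + copies * genome_mass


def read_fasta_constructs(
    path: str | Path, per_base_mass: float = DEFAULT_PER_BASE_MASS
) -> list[GenomeConstruct]:
    """Load constructs (with sequences) from a FASTA file."""
    constructs = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq).upper()
        constructs.append(
            GenomeConstruct(record.id, len(seq), sequence=seq, per_base_mass=per_base_mass)
        )
    return constructs


def read_construct_table(
    path: str | Path, per_base_mass: float = DEFAULT_PER_BASE_MASS
) -> list[GenomeConstruct]:
    """Load a delimited (name, n_bases) table; '#' lines are comments."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if not {"name", "n_bases"} <= set(df.columns):
        raise ValueError("construct table needs columns 'name' and 'n_bases'")
    return [
        GenomeConstruct(str(row["name"]), int(row["n_bases"]), per_base_mass=per_base_mass)
        for _, row in df.iterrows()
    ]


def aav8_construct_table(per_base_mass: float = DEFAULT_PER_BASE_MASS) -> list[GenomeConstruct]:
    """The eight bundled AAV8 vector constructs (name, base count incl. ITRs)."""
    return [
        GenomeConstruct(name, n_bases, per_base_mass=per_base_mass)
        for name, n_bases in AAV8_CONSTRUCTS
    ]
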