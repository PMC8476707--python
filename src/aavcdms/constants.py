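"""Physical constants and AAV8 reference values used across the package.

Masses are average (isotope-abundance-weighted) masses in daltons unless
stated otherwise.
"""

from __future__ import annotations

PROTON_MASS = 1.007276
"""Mass removed per deprotonated (ionized) backbone phosphate, Da."""

WATER_MASS = 18.01528
"""Terminal-group mass added per free strand end (condensation bookkeeping), Da."""

DNA_RESIDUE_AVG_MASS = {
    "A": 313.21,
    "C": 289.18,
    "G": 329.21,
    "T": 304.20,
}
"""Average chain-residue masses of the deoxynucleotides (nucleoside
monophosphate minus water), Da."""

MEAN_IONIZED_RESIDUE_MASS = (
    sum(DNA_RESIDUE_AVG_MASS.values()) / len(DNA_RESIDUE_AVG_MASS) - PROTON_MASS
)
"""Mean ionized deoxynucleotide residue mass at 50% GC (~307.94 Da)."""

DEFAULT_PER_BASE_MASS = 307.96
"""Default per-nucleotide mass of an ionized ssDNA strand (strand-averaged), Da.

Back-computed from the published vector-mass table: 307.96 is inside the
narrow interval (307.945-307.980 Da) consistent with every printed value at
3-decimal MDa rounding, and within 0.02 Da of the chemically derived
``MEAN_IONIZED_RESIDUE_MASS``.  Configurable everywhere it is used.
"""

# --- AAV8 capsid ---------------------------------------------------------

AAV8_VP_MASSES = (81667.0, 66692.0, 59805.0)
"""VP1, VP2, VP3 sequence masses for AAV8, Da."""

AAV8_VP_RATIO = (1.0, 1.0, 10.0)
"""Nominal VP1:VP2:VP3 ratio for capsids from HEK293-style expression."""

CAPSID_N_SUBUNITS = 60

AAV8_CAPACITY_DA = 5.33e6
"""Apparent packaging-capacity particle mass for AAV8, Da."""

# --- common counterions --------------------------------------------------

CATION_MASSES = {
    "Na": (22.98977, 1),
    "NH4": (18.03846, 1),
    "Mg": (24.305, 2),
    "H": (1.00794, 1),
}
"""Cation name -> (average mass Da, valence)."""

AMMONIUM_MASS = CATION_MASSES["NH4"][0]
ACETATE_MASS = 59.044
"""Acetate anion average mass, Da (the electrospray buffer counteranion)."""

# --- vector constructs (name, number of bases incl. ITRs) ----------------

AAV8_CONSTRUCTS = (
    ("CMV-CRE", 2219),
    ("CMV-GFP", 2544),
    ("CMV-mCherry", 2784),
    ("CAG-GFP", 2876),
    ("CAG-mCherry", 2895),
    ("EF1a-GFP", 3458),
    ("CBA-GFP", 4354),
    ("CMV-SaCas9", 4844),
)

AAV8_CONSTRUCT_EXPECTED_MDA = {
    "CMV-CRE": 0.683,
    "CMV-GFP": 0.783,
    "CMV-mCherry": 0.857,
    "CAG-GFP": 0.886,
    "CAG-mCherry": 0.892,
    "EF1a-GFP": 1.065,
    "CBA-GFP": 1.341,
    "CMV-SaCas9": 1.492,
}
"""Published expected genome masses (MDa, strand-averaged ionized ssDNA)."""
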