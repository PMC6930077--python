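"""Physicochemical constant tables used across the pipeline.

The tables are deliberately plain module-level mappings: analyses log them
for provenance, and the pI/pK set can be overridden per call, so nothing
here is mutated at run time.
"""

from types import MappingProxyType

#: Kyte-Doolittle hydropathy values, one per standard residue.
#: Positive = hydrophobic.  Used as the per-residue scale behind the
#: mean-hydrophobicity (GRAVY) statistic.
KYTE_DOOLITTLE = MappingProxyType({
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
})

#: EMBOSS default pK values for the nine ionizable groups used in the
#: isoelectric-point calculation.  "nterm"/"cterm" are the free termini.
EMBOSS_PK = MappingProxyType({
    "nterm": 8.6, "cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
})

#: Groups positively charged below their pK (basic side).
BASIC_GROUPS = ("nterm", "K", "R", "H")
#: Groups negatively charged above their pK (acidic side).
ACIDIC_GROUPS = ("cterm", "D", "E", "C", "Y")

#: Residue classes used for CDR3 composition profiling.  Histidine is a
#: member of both the polar and the aromatic class, so the three class
#: fractions of a sequence may sum above 1.
RESIDUE_CLASSES = MappingProxyType({
    "polar": frozenset("DEHKNQRST"),
    "aliphatic": frozenset("AILV"),
    "aromatic": frozenset("FHWY"),
})

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
NT_ALPHABET = "ACGT"

#: Canonical mouse iNKT alpha junction (Valpha14-Jalpha18), 15 aa,
#: Cys...Phe delimited.  Default for the simulator's invariant alpha chain.
CANONICAL_CDR3A = "CVVGDRGSALGRLHF"
CANONICAL_TRAV = "TRAV11"
CANONICAL_TRAJ = "TRAJ18"
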