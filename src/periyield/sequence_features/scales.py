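"""Per-residue scales, pKa values and residue-group definitions.

These tables are the documented, configurable basis of the default feature
registry and of the default property-predictor suite.  All scales are keyed
by single-letter amino-acid code over the 20-letter alphabet.
"""

from __future__ import annotations

ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

# Kyte-Doolittle hydropathy (J. Mol. Biol. 157:105, 1982).
KYTE_DOOLITTLE = {
    "A": 1.8, "C": 2.5, "D": -3.5, "E": -3.5, "F": 2.8,
    "G": -0.4, "H": -3.2, "I": 4.5, "K": -3.9, "L": 3.8,
    "M": 1.9, "N": -3.5, "P": -1.6, "Q": -3.5, "R": -4.5,
    "S": -0.8, "T": -0.7, "V": 4.2, "W": -0.9, "Y": -1.3,
}

# Chou-Fasman secondary-structure propensities (helix / sheet / turn-coil).
CHOU_FASMAN_HELIX = {
    "A": 1.42, "C": 0.70, "D": 1.01, "E": 1.51, "F": 1.13,
    "G": 0.57, "H": 1.00, "I": 1.08, "K": 1.16, "L": 1.21,
    "M": 1.45, "N": 0.67, "P": 0.57, "Q": 1.11, "R": 0.98,
    "S": 0.77, "T": 0.83, "V": 1.06, "W": 1.08, "Y": 0.69,
}
CHOU_FASMAN_SHEET = {
    "A": 0.83, "C": 1.19, "D": 0.54, "E": 0.37, "F": 1.38,
    "G": 0.75, "H": 0.87, "I": 1.60, "K": 0.74, "L": 1.30,
    "M": 1.05, "N": 0.89, "P": 0.55, "Q": 1.10, "R": 0.93,
    "S": 0.75, "T": 1.19, "V": 1.70, "W": 1.37, "Y": 1.47,
}
CHOU_FASMAN_COIL = {
    "A": 0.66, "C": 1.19, "D": 1.46, "E": 0.74, "F": 0.60,
    "G": 1.56, "H": 0.95, "I": 0.47, "K": 1.01, "L": 0.59,
    "M": 0.60, "N": 1.56, "P": 1.52, "Q": 0.98, "R": 0.95,
    "S": 1.43, "T": 0.96, "V": 0.50, "W": 0.96, "Y": 1.14,
}

# Representative mean residue contact numbers (buried residues contact more
# neighbours); used by the default contact-number property predictor.
CONTACT_NUMBER = {
    "A": 7.0, "C": 8.3, "D": 5.4, "E": 5.5, "F": 8.3,
    "G": 6.8, "H": 6.6, "I": 8.3, "K": 5.0, "L": 8.1,
    "M": 7.9, "N": 5.7, "P": 5.7, "Q": 5.6, "R": 5.4,
    "S": 6.3, "T": 6.5, "V": 8.2, "W": 7.9, "Y": 7.2,
}

# EMBOSS pKa set used for the isoelectric-point bisection.
PKA_POSITIVE = {"K": 10.8, "R": 12.5, "H": 6.5}
PKA_NEGATIVE = {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1}
PKA_NTERM = 8.6
PKA_CTERM = 3.6

# Disorder-promoting residues (Dunker-style set) for the default
# disordered-residue-count predictor.
DISORDER_PROMOTING = frozenset("ARSQEGKP")

# Exposed accessibility class, also the default exposed-fraction predictor.
EXPOSED_RESIDUES = frozenset("RKQEND")

# Named physicochemical residue groups.  The first block carries the groups
# that the selected feature subsets refer to by name; the remaining 21 are
# the standard three-state composition/transition/distribution classes
# (hydropathy, van der Waals volume, polarity, polarizability, charge,
# secondary structure, solvent accessibility).  Together with the 20
# per-residue frequencies and max-runs, length, charge, pI and the 11
# predicted properties they make up the 122 base features.
GROUP_DEFINITIONS: tuple[tuple[str, str], ...] = (
    ("basic_positive", "HKR"),
    ("acidic_negative", "DE"),
    ("sulfur", "CM"),
    ("aliphatic", "ILVAG"),
    ("nonpolar_hydrophilic", "ILVAGP"),
    ("aromatic", "FWY"),
    ("hydroxyl", "STY"),
    ("amide", "NQ"),
    ("tiny", "AGS"),
    ("small", "ACDGNPSTV"),
    ("hydrophobic_kd", "ACFILMV"),
    ("charged", "DEHKR"),
    ("polar_uncharged", "CNQSTY"),
    ("hydropathy_polar", "RKEDQN"),
    ("hydropathy_neutral", "GASTPHY"),
    ("hydropathy_hydrophobic", "CLVIMFW"),
    ("vdw_small", "GASTPDC"),
    ("vdw_medium", "NVEQIL"),
    ("vdw_large", "MHKFRYW"),
    ("polarity_low", "LIFWCMVY"),
    ("polarity_medium", "PATGS"),
    ("polarity_high", "HQRKNED"),
    ("polarizability_low", "GASDT"),
    ("polarizability_medium", "CPNVEQIL"),
    ("polarizability_high", "KMHFRYW"),
    ("charge_positive", "KR"),
    ("charge_neutral", "ANCQGHILMFPSTWYV"),
    ("charge_negative", "DE"),
    ("ss_helix", "EALMQKRH"),
    ("ss_strand", "VIYCWFT"),
    ("ss_coil", "GNPSD"),
    ("acc_buried", "ALFCGIVW"),
    ("acc_exposed", "RKQEND"),
    ("acc_intermediate", "MSPTHY"),
)
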