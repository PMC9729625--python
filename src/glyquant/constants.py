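"""Physical constants and composition tables.

All masses are monoisotopic and in Da. Elemental isotope masses and abundances
follow the standard reference tables (CODATA / IUPAC 2013 isotopic
compositions, truncated to the precision relevant at ppm-level mass accuracy).
"""

from __future__ import annotations

PROTON_MASS = 1.007276466

#: average spacing between adjacent isotopologue aggregates for CHNOS
#: biomolecules (dominated by the 13C-12C mass difference)
NEUTRON_SPACING = 1.00286

# element -> list of (isotope mass, abundance), most abundant first
ISOTOPES: dict[str, list[tuple[float, float]]] = {
    "C": [(12.0, 0.9893), (13.00335483507, 0.0107)],
    "H": [(1.00782503224, 0.999885), (2.01410177812, 0.000115)],
    "N": [(14.00307400443, 0.99636), (15.00010889888, 0.00364)],
    "O": [
        (15.99491461957, 0.99757),
        (16.99913175650, 0.00038),
        (17.99915961286, 0.00205),
    ],
    "S": [
        (31.9720711744, 0.9499),
        (32.9714589098, 0.0075),
        (33.967867004, 0.0425),
        (35.96708071, 0.0001),
    ],
}

# amino-acid residue elemental compositions (dehydrated, i.e. in-chain)
RESIDUE_FORMULAS: dict[str, dict[str, int]] = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}
# J denotes the glycosylated Asn in glyco search engines
RESIDUE_FORMULAS["J"] = RESIDUE_FORMULAS["N"]

WATER = {"H": 2, "O": 1}

# dehydrated (in-glycan) monosaccharide residue formulas
MONOSACCHARIDE_FORMULAS: dict[str, dict[str, int]] = {
    "Hex": {"C": 6, "H": 10, "O": 5},
    "HexNAc": {"C": 8, "H": 13, "N": 1, "O": 5},
    "NeuAc": {"C": 11, "H": 17, "N": 1, "O": 8},
    "NeuGc": {"C": 11, "H": 17, "N": 1, "O": 9},
    "Fuc": {"C": 6, "H": 10, "O": 4},
}

MONOSACCHARIDE_MASSES: dict[str, float] = {
    "Hex": 162.0528,
    "HexNAc": 203.0794,
    "NeuAc": 291.0954,
    "NeuGc": 307.0903,
    "Fuc": 146.0579,
}

# single-letter glycan codes used in H(5)N(4)A(2)-style composition strings
# and in canonical structure strings
GLYCAN_LETTER_CODES: dict[str, str] = {
    "H": "Hex",
    "N": "HexNAc",
    "A": "NeuAc",
    "G": "NeuGc",
    "F": "Fuc",
}

SIALIC_ACIDS = frozenset({"NeuAc", "NeuGc"})

# named peptide modifications with elemental formulas
MODIFICATION_FORMULAS: dict[str, dict[str, int]] = {
    "Carbamidomethyl": {"C": 2, "H": 3, "N": 1, "O": 1},
    "Oxidation": {"O": 1},
    "Acetyl": {"C": 2, "H": 2, "O": 1},
    "Deamidated": {"H": -1, "N": -1, "O": 1},
}

# SILAC label mass shifts (Da) keyed by label name; applied per labelled residue
SILAC_LABELS: dict[str, tuple[str, float]] = {
    # label -> (residue, mass shift)
    "K4": ("K", 4.025107),
    "K6": ("K", 6.020129),
    "K8": ("K", 8.014199),
    "R6": ("R", 6.020129),
    "R10": ("R", 10.008269),
}

# TMT 6-plex reporter ion m/z (singly protonated reporter fragments)
TMT6_REPORTERS: dict[str, float] = {
    "126": 126.127726,
    "127": 127.124761,
    "128": 128.134436,
    "129": 129.131471,
    "130": 130.141145,
    "131": 131.138180,
}
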