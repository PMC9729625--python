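"""Predict the isotopologue envelope of an intact glycopeptide.

Prints the m/z grid and relative abundances of a sialylated biantennary
glycopeptide at charge 2, and the cosine similarity between the neutral and
mono-sialylated envelopes — the statistic the in-run glycoform search is
built on."""

import numpy as np

from glyquant.isotope import cosine_similarity, emass_pattern, glycopeptide_formula

peptide = "JSSEELNSNK"  # J marks the glycosylated Asn
glycan = {"Hex": 5, "HexNAc": 4, "NeuAc": 2}

formula = glycopeptide_formula(peptide, glycan=glycan)
print("elemental composition:", dict(sorted(formula.items())))

pattern = emass_pattern(formula, charge=2, n_peaks=6)
for mz, ab in zip(pattern.mz, pattern.abundance):
    print(f"  m/z {mz:10.4f}   abundance {ab:.4f}")

neutral = emass_pattern(
    glycopeptide_formula(peptide, glycan={"Hex": 5, "HexNAc": 4}), charge=2, n_peaks=6
)
sim = cosine_similarity(pattern.abundance, neutral.abundance)
print(f"envelope cosine, 2SA vs 0SA glycoform: {sim:.4f}")
print("(similar shapes: the mass shift, not the envelope, separates glycoforms)")
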