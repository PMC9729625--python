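"""Theoretical isotope envelopes by stepwise convolution.

A glycopeptide's elemental composition is assembled from residue, water,
glycan-monomer and modification formulas; its aggregated (centroided)
isotopologue pattern is computed by the stepwise-convolution approach of the
emass algorithm: per-element single-atom distributions are raised to the
element count by repeated squaring, convolved across elements, and binned by
nominal neutron number with abundance-weighted mean masses per bin.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .constants import (
    ISOTOPES,
    MODIFICATION_FORMULAS,
    MONOSACCHARIDE_FORMULAS,
    PROTON_MASS,
    RESIDUE_FORMULAS,
    WATER,
)
from .model import IsotopePattern

#: relative-abundance pruning threshold during convolution
PRUNE_THRESHOLD = 1e-10


def glycopeptide_formula(
    peptide: str,
    modifications: list[tuple[int, str, float]] | None = None,
    glycan: dict[str, int] | None = None,
) -> dict[str, int]:
    """Elemental composition of an intact (glyco)peptide.

    Sum of in-chain residue formulas plus one water, plus dehydrated
    monosaccharide formulas for the glycan, plus named modification formulas.
    ``J`` is accepted as the glycosylated asparagine.
    """
    if not peptide:
        raise ValueError("empty peptide sequence")
    counts: Counter[str] = Counter(WATER)
    for aa in peptide:
        try:
            formula = RESIDUE_FORMULAS[aa]
        except KeyError:
            raise ValueError(f"unknown residue {aa!r} in peptide {peptide!r}")
        counts.update(formula)
    for _pos, name, _mass in modifications or []:
        try:
            formula = MODIFICATION_FORMULAS[name]
        except KeyError:
            raise ValueError(f"unknown modification {name!r}")
        for el, n in formula.items():
            counts[el] += n
    for mono, n in (glycan or {}).items():
        if n == 0:
            continue
        try:
            formula = MONOSACCHARIDE_FORMULAS[mono]
        except KeyError:
            raise ValueError(f"unknown monosaccharide {mono!r}")
        for el, k in formula.items():
            counts[el] += k * n
    if any(v < 0 for v in counts.values()):
        raise ValueError("modification formulas drove an element count negative")
    return {el: n for el, n in counts.items() if n}


def monoisotopic_mass(formula: dict[str, int]) -> float:
    return sum(ISOTOPES[el][0][0] * n for el, n in formula.items())


def _element_pattern(element: str) -> tuple[np.ndarray, np.ndarray]:
    """Single-atom distribution binned by nominal neutron shift."""
    isotopes = ISOTOPES[element]
    mono = isotopes[0][0]
    nbins = max(int(round(m - mono)) for m, _ in isotopes) + 1
    mass = np.zeros(nbins)
    abund = np.zeros(nbins)
    for m, p in isotopes:
        k = int(round(m - mono))
        # weighted-mean accumulation (relevant only if two isotopes share a bin)
        mass[k] = (mass[k] * abund[k] + m * p) / (abund[k] + p)
        abund[k] += p
    return mass, abund


def _convolve(
    a: tuple[np.ndarray, np.ndarray],
    b: tuple[np.ndarray, np.ndarray],
    max_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Convolve two binned distributions, tracking abundance-weighted masses."""
    ma, pa = a
    mb, pb = b
    n = min(len(pa) + len(pb) - 1, max_bins)
    abund = np.zeros(n)
    wmass = np.zeros(n)
    for i in range(len(pa)):
        if pa[i] <= 0:
            continue
        jmax = min(len(pb), n - i)
        contrib = pa[i] * pb[:jmax]
        abund[i : i + jmax] += contrib
        wmass[i : i + jmax] += contrib * (ma[i] + mb[:jmax])
    mass = np.where(abund > 0, wmass / np.maximum(abund, 1e-300), 0.0)
    # prune negligible bins to keep the stepwise products sparse
    keep = abund >= PRUNE_THRESHOLD * abund.max()
    abund[~keep] = 0.0
    return mass, abund


def _element_power(
    element: str, count: int, max_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Distribution of `count` atoms of one element by repeated squaring."""
    base = _element_pattern(element)
    result: tuple[np.ndarray, np.ndarray] | None = None
    while count:
        if count & 1:
            result = base if result is None else _convolve(result, base, max_bins)
        count >>= 1
        if count:
            base = _convolve(base, base, max_bins)
    assert result is not None
    return result


def emass_pattern(
    formula: dict[str, int], charge: int, n_peaks: int = 6
) -> IsotopePattern:
    """Aggregated isotopologue pattern of a formula at the given charge.

    Returns the first ``n_peaks`` isotopologue aggregates with abundances
    normalized so the most abundant equals 1 and m/z values computed from the
    abundance-weighted aggregate neutral masses.
    """
    if not formula or not any(formula.values()):
        raise ValueError("empty elemental composition")
    if charge < 1 or n_peaks < 1:
        raise ValueError("charge and n_peaks must be >= 1")
    max_bins = n_peaks + 4  # headroom so edge bins aggregate correctly
    total: tuple[np.ndarray, np.ndarray] | None = None
    for el, count in sorted(formula.items()):
        if count == 0:
            continue
        if el not in ISOTOPES:
            raise ValueError(f"no isotope table for element {el!r}")
        part = _element_power(el, count, max_bins)
        total = part if total is None else _convolve(total, part, max_bins)
    mass, abund = total
    mass, abund = mass[:n_peaks], abund[:n_peaks]
    abund = abund / abund.max()
    mz = (mass + charge * PROTON_MASS) / charge
    return IsotopePattern(mz=mz, abundance=abund, charge=charge)


def cosine_similarity(x: np.ndarray, y: np.ndarray) -> float:
    """Cosine of the angle between two abundance vectors.

    Defined as 0 when either vector is all-zero (no shared evidence).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("envelope vectors differ in length")
    nx = np.linalg.norm(x)
    ny = np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(np.dot(x, y) / (nx * ny))
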