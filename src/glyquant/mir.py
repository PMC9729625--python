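"""Match In Run: quantifying sialylated/desialylated glycoforms in one run.

Glycan structures are held as canonical strings: a depth-first parenthesized
tree over single-letter monosaccharide codes (H=Hex, N=HexNAc, A=NeuAc,
G=NeuGc, F=Fuc), children ordered by their subtree string so every tree has
exactly one canonical form, e.g. ``(N(N(H(H(N(H)))(H(N(H))))))`` for the
biantennary H(5)N(4) backbone.

Structures sharing the same *infrastructure* — the structure with all sialic
acid units removed — form a subnet. For an identified glycopeptide whose
glycan lies in a subnet, every other subnet member yields a candidate
glycopeptide at a mass-shifted m/z and an RT shifted by the per-sialic-acid
retention bias. Candidates are detected by per-MS1-scan cosine matching of
theoretical vs experimental isotope envelopes (Sim_iso), and an evidence is
kept only when the best scan exceeds 0.9, extended while Sim_iso stays at or
above 0.9; its MIR score is the sum of the retained similarities.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import GLYCAN_LETTER_CODES, MONOSACCHARIDE_MASSES
from .isotope import cosine_similarity, emass_pattern, glycopeptide_formula
from .model import GPSM, Evidence, IsotopePattern, Run, Scan

SIALIC_CODES = frozenset({"A", "G"})
SIM_ISO_GATE = 0.9


# ---------------------------------------------------------------------------
# canonical structure strings
# ---------------------------------------------------------------------------


@dataclass
class _Node:
    code: str
    children: list["_Node"] = field(default_factory=list)


def _parse_node(text: str, pos: int) -> tuple[_Node, int]:
    if text[pos] != "(":
        raise ValueError(f"expected '(' at position {pos} in {text!r}")
    pos += 1
    code = text[pos]
    if code not in GLYCAN_LETTER_CODES:
        raise ValueError(f"unknown monosaccharide code {code!r} in {text!r}")
    pos += 1
    node = _Node(code)
    while pos < len(text) and text[pos] == "(":
        child, pos = _parse_node(text, pos)
        node.children.append(child)
    if pos >= len(text) or text[pos] != ")":
        raise ValueError(f"unbalanced parentheses in {text!r}")
    return node, pos + 1


def _canonical(node: _Node) -> str:
    inner = sorted(_canonical(c) for c in node.children)
    return "(" + node.code + "".join(inner) + ")"


def _composition(node: _Node) -> dict[str, int]:
    counts: dict[str, int] = {}

    def walk(n: _Node) -> None:
        name = GLYCAN_LETTER_CODES[n.code]
        counts[name] = counts.get(name, 0) + 1
        for c in n.children:
            walk(c)

    walk(node)
    return counts


@dataclass
class GlycanStructure:
    canonical: str
    _tree: _Node = field(repr=False, compare=False, default=None)

    @classmethod
    def parse(cls, text: str) -> "GlycanStructure":
        node, end = _parse_node(text.strip(), 0)
        if end != len(text.strip()):
            raise ValueError(f"trailing characters in structure {text!r}")
        return cls(canonical=_canonical(node), _tree=node)

    @property
    def tree(self) -> _Node:
        if self._tree is None:
            self._tree, _ = _parse_node(self.canonical, 0)
        return self._tree

    @property
    def composition(self) -> dict[str, int]:
        return _composition(self.tree)

    @property
    def n_sialic(self) -> int:
        comp = self.composition
        return comp.get("NeuAc", 0) + comp.get("NeuGc", 0)


def strip_sialic(g: GlycanStructure) -> str:
    """Canonical string of the structure with all sialic-acid units removed.

    A sialic acid carrying children is a structural error (terminal residues
    only).
    """

    def strip(node: _Node) -> _Node:
        kept = []
        for c in node.children:
            if c.code in SIALIC_CODES:
                if c.children:
                    raise ValueError(
                        f"sialic acid with children in {g.canonical!r}"
                    )
                continue
            kept.append(strip(c))
        return _Node(node.code, kept)

    if g.tree.code in SIALIC_CODES:
        raise ValueError("structure rooted at a sialic acid")
    return _canonical(strip(g.tree))


@dataclass
class Subnet:
    infrastructure: str
    members: list[GlycanStructure]


def build_subnets(db: list[GlycanStructure]) -> list[Subnet]:
    """Partition a glycan database by sialic-acid-stripped infrastructure."""
    if not db:
        raise ValueError("empty glycan database")
    groups: dict[str, dict[str, GlycanStructure]] = {}
    for g in db:
        groups.setdefault(strip_sialic(g), {})[g.canonical] = g
    return [
        Subnet(infra, [members[c] for c in sorted(members)])
        for infra, members in sorted(groups.items())
    ]


def _has_lacnac(node: _Node, parent_code: str | None = None) -> bool:
    if (
        node.code == "N"
        and parent_code == "H"
        and any(c.code == "H" for c in node.children)
    ):
        return True
    return any(_has_lacnac(c, node.code) for c in node.children)


def screen_lacnac(db: list[GlycanStructure]) -> list[GlycanStructure]:
    """Keep structures with at least one LacNAc (Gal–GlcNAc) antenna unit.

    A LacNAc unit is a HexNAc attached to a core/antenna Hex that itself
    carries a Hex — the antenna pattern of complex and hybrid N-glycans.
    Oligomannose structures have no such unit and are screened out.
    """
    return [g for g in db if _has_lacnac(g.tree)]


def load_glycan_db(path: str) -> list[GlycanStructure]:
    """Read a glycan DB file: one canonical string per line, # comments."""
    db = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                db.append(GlycanStructure.parse(line))
    return db


# ---------------------------------------------------------------------------
# retention-time bias of sialic acids
# ---------------------------------------------------------------------------


def estimate_sa_rt_shift(ids: list[GPSM]) -> float | None:
    """Median retention-time shift per sialic acid among identified pairs.

    Pairs share peptide, modifications and charge and have glycan
    compositions identical after removing sialic acids; the estimate is the
    median of ΔRT/ΔSA over all such pairs. Returns None (with a warning) when
    no qualifying pair exists.
    """
    groups: dict[tuple, list[GPSM]] = {}
    for g in ids:
        comp = {
            k: v
            for k, v in g.glycan_composition.items()
            if k not in ("NeuAc", "NeuGc") and v
        }
        key = (
            g.peptide,
            tuple(sorted(g.modifications)),
            g.charge,
            tuple(sorted(comp.items())),
        )
        groups.setdefault(key, []).append(g)
    shifts = []
    for members in groups.values():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                sa = lambda g: g.glycan_composition.get("NeuAc", 0) + g.glycan_composition.get("NeuGc", 0)
                dsa = sa(a) - sa(b)
                if dsa != 0:
                    shifts.append((a.rt - b.rt) / dsa)
    if not shifts:
        warnings.warn("no identified pairs qualify for SA RT-shift estimation")
        return None
    return float(statistics.median(shifts))


# ---------------------------------------------------------------------------
# candidates and in-run search
# ---------------------------------------------------------------------------


@dataclass
class Candidate:
    """A glycopeptide candidate generated from an identified anchor."""

    anchor: GPSM
    glycan: GlycanStructure
    composition: dict[str, int]
    precursor_mz: float
    expected_rt: float
    delta_sa: int

    @property
    def key(self) -> tuple:
        comp = tuple(sorted((k, v) for k, v in self.composition.items() if v))
        return (self.anchor.peptide, comp, self.anchor.charge)


def _composition_mass(counts: dict[str, int]) -> float:
    return sum(MONOSACCHARIDE_MASSES[k] * v for k, v in counts.items())


def candidates_for(
    gpsm: GPSM,
    subnets: list[Subnet],
    sa_rt_shift: float = 0.0,
) -> list[Candidate]:
    """Candidate glycopeptides for an identified anchor, one per other subnet
    member.

    The anchor's glycan is matched to a subnet by structure when available,
    otherwise by composition. Candidate precursors shift by the composition
    mass difference over the charge; expected RT shifts by ΔSA times the
    per-sialic-acid retention bias.
    """
    matched = None
    anchor_member = None
    for subnet in subnets:
        for member in subnet.members:
            if gpsm.glycan_structure:
                if member.canonical == GlycanStructure.parse(gpsm.glycan_structure).canonical:
                    matched, anchor_member = subnet, member
                    break
            elif member.composition == gpsm.glycan_composition:
                matched, anchor_member = subnet, member
                break
        if matched:
            break
    if matched is None:
        return []
    sa = lambda comp: comp.get("NeuAc", 0) + comp.get("NeuGc", 0)
    anchor_mass = _composition_mass(anchor_member.composition)
    out = []
    for member in matched.members:
        if member.canonical == anchor_member.canonical:
            continue
        comp = member.composition
        dmass = _composition_mass(comp) - anchor_mass
        dsa = sa(comp) - sa(anchor_member.composition)
        out.append(
            Candidate(
                anchor=gpsm,
                glycan=member,
                composition=comp,
                precursor_mz=gpsm.precursor_mz + dmass / gpsm.charge,
                expected_rt=gpsm.rt + dsa * sa_rt_shift,
                delta_sa=dsa,
            )
        )
    return out


@dataclass
class MIREvidence:
    candidate: Candidate
    evidence: Evidence
    score_mir: float
    per_scan_sim: np.ndarray

    @property
    def intensity(self) -> float:
        return self.evidence.mono_area


def _closest_peak(scan: Scan, target_mz: float, tol_ppm: float) -> float:
    """Intensity of the peak with the closest mass within ±tol_ppm, else 0."""
    lo = target_mz * (1.0 - tol_ppm * 1e-6)
    hi = target_mz * (1.0 + tol_ppm * 1e-6)
    i0, i1 = np.searchsorted(scan.mz, [lo, hi])
    if i0 == i1:
        return 0.0
    idx = i0 + int(np.argmin(np.abs(scan.mz[i0:i1] - target_mz)))
    return float(scan.intensity[idx])


def candidate_pattern(candidate: Candidate, n_peaks: int = 6) -> IsotopePattern:
    g = candidate.anchor
    formula = glycopeptide_formula(g.peptide, g.modifications, candidate.composition)
    return emass_pattern(formula, g.charge, n_peaks)


def mir_search(
    run: Run,
    candidate: Candidate,
    rt_window: tuple[float, float],
    tol_ppm: float = 20.0,
    n_peaks: int = 6,
) -> MIREvidence | None:
    """Detect a candidate glycoform inside one run by envelope matching.

    For every MS1 scan in the window, the experimental envelope Y collects the
    closest-mass peak within ±tol_ppm of each theoretical isotopologue, and
    Sim_iso is the cosine between Y and the theoretical envelope X. If the
    best scan exceeds 0.9, the evidence spans the maximal contiguous range of
    scans with Sim_iso ≥ 0.9 around it; its intensity is the mono-peak area
    over that span and its MIR score the sum of the retained similarities.
    """
    lo, hi = rt_window
    pattern = candidate_pattern(candidate, n_peaks)
    ms1 = run.ms1_scans
    idx = [i for i, s in enumerate(ms1) if lo <= s.rt < hi]
    if not idx:
        return None
    envelopes = np.array(
        [
            [_closest_peak(ms1[i], mz, tol_ppm) for mz in pattern.mz]
            for i in idx
        ]
    )
    sims = np.array(
        [cosine_similarity(pattern.abundance, env) for env in envelopes]
    )
    seed = int(np.argmax(sims))
    if sims[seed] <= SIM_ISO_GATE:
        return None
    left = seed
    while left > 0 and sims[left - 1] >= SIM_ISO_GATE:
        left -= 1
    right = seed
    while right < len(sims) - 1 and sims[right + 1] >= SIM_ISO_GATE:
        right += 1
    kept = slice(left, right + 1)
    rts = np.array([ms1[i].rt for i in idx[kept]])
    intensities = envelopes[kept].T  # [n_isotopes, n_scans]
    mono_area = float(np.trapezoid(intensities[0], rts)) if len(rts) > 1 else float(intensities[0, 0])
    profile = intensities.sum(axis=0)
    evidence = Evidence(
        ref=f"mir:{candidate.key}",
        rt=rts,
        intensities=intensities,
        apex_scan=int(np.argmax(profile)),
        trigger_scan=seed - left,
        mono_area=mono_area,
        pattern=pattern,
    )
    return MIREvidence(
        candidate=candidate,
        evidence=evidence,
        score_mir=float(sims[kept].sum()),
        per_scan_sim=sims[kept].copy(),
    )
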