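"""Seeded synthetic LC-MS runs with ground truth.

The generator emulates the benchmark designs the engine is validated on:
Gaussian elution peaks carrying theoretical isotope envelopes over centroided
MS1 scans, lognormal multiplicative noise and random interference peaks,
two-sample disjoint inventories (entrapment), spiked sialylated glycoform
series over a high-mannose background (the MIR benchmark), SILAC mass-shifted
channel pairs and TMT reporter-ion MS2 scans. Every generator is a pure
function of its spec and seed.

True areas refer to the monoisotopic trace: each isotopologue trace is a
Gaussian scaled so the analytic integral of the mono trace equals the item's
``area`` (intensity·minutes) before noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import PROTON_MASS, SILAC_LABELS, TMT6_REPORTERS
from .isotope import emass_pattern, glycopeptide_formula, monoisotopic_mass
from .mir import GlycanStructure
from .model import GPSM, Run, Scan

GAUSS_FWHM = 2.0 * np.sqrt(2.0 * np.log(2.0))

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

COMPLEX_GLYCANS = [
    {"Hex": 5, "HexNAc": 4},
    {"Hex": 5, "HexNAc": 4, "NeuAc": 1},
    {"Hex": 5, "HexNAc": 4, "NeuAc": 2},
    {"Hex": 4, "HexNAc": 4, "Fuc": 1},
    {"Hex": 6, "HexNAc": 5},
    {"Hex": 5, "HexNAc": 4, "Fuc": 1},
    {"Hex": 3, "HexNAc": 4, "Fuc": 1},
]

#: biantennary H(5)N(4) backbone and its sialylated forms
BIANTENNARY_0SA = "(N(N(H(H(N(H)))(H(N(H))))))"
BIANTENNARY_1SA = "(N(N(H(H(N(H(A))))(H(N(H))))))"
BIANTENNARY_2SA = "(N(N(H(H(N(H(A))))(H(N(H(A)))))))"
HIGH_MANNOSE = [
    "(N(N(H(H(H))(H(H)))))",  # H(5)N(2)
    "(N(N(H(H(H(H)))(H(H(H))))))",  # H(7)N(2)
    "(N(N(H(H(H(H(H))))(H(H(H(H)))))))",  # H(9)N(2)
]


@dataclass
class InventoryItem:
    peptide: str
    glycan: dict[str, int]
    charge: int
    rt: float  # true apex, minutes
    area: float  # true mono-trace area, intensity * minutes
    fwhm: float  # minutes
    protein: str = "SYNPROT"
    glycosite: int = 1
    modifications: list = field(default_factory=list)
    structure: str | None = None
    identify: bool | None = None  # None = follow spec.id_probability
    mass_offset: float = 0.0  # Da, e.g. SILAC label shift
    channel: str = ""

    def __post_init__(self) -> None:
        if self.area <= 0 or self.fwhm <= 0:
            raise ValueError("area and FWHM must be positive")


@dataclass
class SimSpec:
    inventory: list[InventoryItem]
    gradient_minutes: float = 20.0
    ms1_interval_s: float = 2.0
    noise_baseline: float = 50.0  # interference-peak intensity scale
    noise_sigma: float = 0.05  # lognormal multiplicative sigma on peak points
    #: mean interference peaks per scan; centroided MS1 scans of complex
    #: samples carry hundreds of low-intensity background centroids
    interference_rate: float = 300.0
    id_probability: float = 0.8
    mz_range: tuple[float, float] = (400.0, 2000.0)
    n_isotopes: int = 6
    seed: int = 0


def _item_pattern(item: InventoryItem, n_isotopes: int):
    formula = glycopeptide_formula(item.peptide, item.modifications, item.glycan)
    pattern = emass_pattern(formula, item.charge, n_isotopes)
    if item.mass_offset:
        pattern = dataclasses.replace(
            pattern, mz=pattern.mz + item.mass_offset / item.charge
        )
    return pattern


def simulate_run(
    spec: SimSpec, run_id: str = "synthetic"
) -> tuple[Run, list[GPSM], pd.DataFrame]:
    """Generate one centroided MS1 run, its identification list and the truth.

    Identifications are emitted near each true apex for a seeded random
    subset of the inventory (``id_probability``), which controls realistic
    missingness for cross-run matching.
    """
    if not spec.inventory:
        raise ValueError("inventory is empty")
    rng = np.random.default_rng(spec.seed)
    n_scans = int(np.floor(spec.gradient_minutes * 60.0 / spec.ms1_interval_s)) + 1
    times = np.arange(n_scans) * spec.ms1_interval_s / 60.0

    prepared = []
    for item in spec.inventory:
        pattern = _item_pattern(item, spec.n_isotopes)
        sigma = item.fwhm / GAUSS_FWHM
        # scale so the mono trace integrates to `area`
        amp = item.area / (sigma * np.sqrt(2.0 * np.pi))
        rel = pattern.abundance / pattern.abundance[0]
        prepared.append((item, pattern, sigma, amp, rel))

    scans = []
    for si, t in enumerate(times):
        mzs: list[float] = []
        intens: list[float] = []
        for item, pattern, sigma, amp, rel in prepared:
            if abs(t - item.rt) > 5.0 * sigma:
                continue
            shape = amp * np.exp(-0.5 * ((t - item.rt) / sigma) ** 2)
            values = shape * rel
            if spec.noise_sigma > 0:
                values = values * np.exp(
                    rng.normal(0.0, spec.noise_sigma, size=len(values))
                )
            mzs.extend(pattern.mz)
            intens.extend(values)
        n_noise = rng.poisson(spec.interference_rate)
        if n_noise:
            mzs.extend(rng.uniform(*spec.mz_range, size=n_noise))
            intens.extend(rng.exponential(spec.noise_baseline, size=n_noise))
        order = np.argsort(mzs)
        mz_arr = np.asarray(mzs, dtype=float)[order]
        in_arr = np.asarray(intens, dtype=float)[order]
        # collapse coincident centroids to keep m/z strictly ascending
        if len(mz_arr) > 1:
            keep = np.concatenate([[True], np.diff(mz_arr) >= 1e-9])
            if not keep.all():
                groups = np.cumsum(keep) - 1
                merged = np.zeros(int(groups[-1]) + 1)
                np.add.at(merged, groups, in_arr)
                mz_arr = mz_arr[keep]
                in_arr = merged
        scans.append(
            Scan(
                scan_id=f"{run_id}.scan.{si + 1}",
                ms_level=1,
                rt=float(t),
                mz=mz_arr,
                intensity=in_arr,
            )
        )

    ids: list[GPSM] = []
    truth_rows = []
    for k, (item, pattern, sigma, amp, rel) in enumerate(prepared):
        emit = (
            item.identify
            if item.identify is not None
            else bool(rng.random() < spec.id_probability)
        )
        formula = glycopeptide_formula(
            item.peptide, item.modifications, item.glycan
        )
        mass = monoisotopic_mass(formula) + item.mass_offset
        if emit:
            ids.append(
                GPSM(
                    run_id=run_id,
                    spectrum_ref=f"{run_id}.id.{k + 1}",
                    peptide=item.peptide,
                    modifications=list(item.modifications),
                    glycan_composition=dict(item.glycan),
                    glycan_structure=item.structure,
                    glycosite=item.glycosite,
                    charge=item.charge,
                    precursor_mz=mass / item.charge + PROTON_MASS,
                    precursor_mass=mass,
                    rt=item.rt,
                    protein=item.protein,
                )
            )
        truth_rows.append(
            {
                "run_id": run_id,
                "peptide": item.peptide,
                "glycan": str(sorted(item.glycan.items())),
                "charge": item.charge,
                "channel": item.channel or run_id,
                "true_rt": item.rt,
                "true_area": item.area,
                "identified": emit,
            }
        )
    return Run(run_id=run_id, scans=scans), ids, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# inventory factories
# ---------------------------------------------------------------------------


def _random_peptide(rng: np.random.Generator, require: str | None = None) -> str:
    length = int(rng.integers(8, 15))
    letters = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), length)]
    site = int(rng.integers(1, length - 1))
    letters[site] = "J"
    if require and require not in letters:
        pos = int(rng.integers(0, length))
        if pos == site:
            pos = (pos + 1) % length
        letters[pos] = require
    return "".join(letters)


DECOY_IMAGE_SHIFT = 10.0  # Da; mirror of the engine's decoy mass shift


def _envelope_collision(a, b, n_isotopes: int = 6, min_gap: float = 0.06) -> bool:
    """Do two co-eluting items have overlapping isotope envelopes?

    Besides the real-vs-real overlap, each item's +10 Da decoy window must
    stay clear of the other's real envelope: the decoy channel then samples
    the same background as a genuinely absent precursor, which is what the
    false-quantitation calibration assumes.
    """
    (mz_a, z_a), (mz_b, z_b) = a, b

    def overlap(mz1, z1, mz2, z2):
        span1 = (mz1 - min_gap, mz1 + n_isotopes * 1.003 / z1 + min_gap)
        span2 = (mz2 - min_gap, mz2 + n_isotopes * 1.003 / z2 + min_gap)
        return span1[0] < span2[1] and span2[0] < span1[1]

    return (
        overlap(mz_a, z_a, mz_b, z_b)
        or overlap(mz_a + DECOY_IMAGE_SHIFT / z_a, z_a, mz_b, z_b)
        or overlap(mz_a, z_a, mz_b + DECOY_IMAGE_SHIFT / z_b, z_b)
    )


def random_inventory(
    n: int,
    rng: np.random.Generator,
    rt_range: tuple[float, float] = (2.0, 18.0),
    fwhm: float = 0.15,
    area_range: tuple[float, float] = (5e3, 5e4),
    rt_exclusion: float = 2.5,
    existing: list[InventoryItem] | None = None,
    require_residue: str | None = None,
) -> list[InventoryItem]:
    """Draw n glycopeptide inventory items with non-colliding envelopes.

    Items whose retention times are within ``rt_exclusion`` minutes (also
    against ``existing`` items) are forced to have disjoint isotope-envelope
    m/z spans, so no two nearby analytes share extraction windows.
    """
    items = list(existing or [])
    made: list[InventoryItem] = []
    used_peptides = {i.peptide for i in items}

    def item_mz(item: InventoryItem) -> float:
        formula = glycopeptide_formula(item.peptide, [], item.glycan)
        return (
            monoisotopic_mass(formula) + item.mass_offset
        ) / item.charge + PROTON_MASS

    placed = [(item_mz(i), i.charge, i.rt) for i in items]
    attempts = 0
    while len(made) < n:
        attempts += 1
        if attempts > 500 * n:
            raise RuntimeError("could not place a collision-free inventory")
        peptide = _random_peptide(rng, require_residue)
        if peptide in used_peptides:
            continue
        glycan = COMPLEX_GLYCANS[int(rng.integers(len(COMPLEX_GLYCANS)))]
        charge = int(rng.choice([2, 3]))
        rt = float(rng.uniform(*rt_range))
        formula = glycopeptide_formula(peptide, [], glycan)
        mz = monoisotopic_mass(formula) / charge + PROTON_MASS
        if not (500.0 <= mz <= 1900.0):
            continue
        clash = False
        for other_mz, other_z, other_rt in placed:
            if abs(other_rt - rt) < rt_exclusion and _envelope_collision(
                (mz, charge), (other_mz, other_z)
            ):
                clash = True
                break
        if clash:
            continue
        placed.append((mz, charge, rt))
        used_peptides.add(peptide)
        made.append(
            InventoryItem(
                peptide=peptide,
                glycan=dict(glycan),
                charge=charge,
                rt=rt,
                area=float(rng.uniform(*area_range)),
                fwhm=fwhm,
                protein=f"SYNPROT{len(items) + len(made) + 1}",
                glycosite=peptide.index("J") + 1,
            )
        )
    return made


def make_entrapment_pair(
    n_per_side: int,
    seed: int = 0,
    gradient_minutes: float = 20.0,
    ms1_interval_s: float = 2.0,
    id_probability: float = 0.9,
    **spec_kwargs,
) -> tuple[Run, list[GPSM], Run, list[GPSM], pd.DataFrame]:
    """Two runs whose glycopeptide inventories are strictly disjoint.

    Cross-side mass coincidences are excluded by construction (co-eluting
    envelopes never share m/z spans across sides), so any cross-run transfer
    is necessarily false.
    """
    if n_per_side < 1:
        raise ValueError("n_per_side must be >= 1")
    rng = np.random.default_rng(seed)
    rt_hi = gradient_minutes - 2.0
    side_a = random_inventory(n_per_side, rng, rt_range=(2.0, rt_hi))
    side_b = random_inventory(
        n_per_side, rng, rt_range=(2.0, rt_hi), existing=side_a
    )
    spec_a = SimSpec(
        inventory=side_a,
        gradient_minutes=gradient_minutes,
        ms1_interval_s=ms1_interval_s,
        id_probability=id_probability,
        seed=seed * 2 + 1,
        **spec_kwargs,
    )
    spec_b = dataclasses.replace(spec_a, inventory=side_b, seed=seed * 2 + 2)
    run_a, ids_a, truth_a = simulate_run(spec_a, run_id="sampleA")
    run_b, ids_b, truth_b = simulate_run(spec_b, run_id="sampleB")
    truth = pd.concat([truth_a, truth_b], ignore_index=True)
    return run_a, ids_a, run_b, ids_b, truth


def make_entrapment_runs(
    n_per_side: int,
    n_replicates: int = 2,
    seed: int = 0,
    gradient_minutes: float = 30.0,
    ms1_interval_s: float = 2.0,
    id_probability: float = 0.8,
    rt_jitter: float = 0.2,
    area_jitter: float = 0.10,
    rt_exclusion: float = 3.5,
    **spec_kwargs,
) -> tuple[list[Run], list[GPSM], dict[str, str], pd.DataFrame]:
    """Replicated two-sample entrapment: disjoint inventories, R runs each.

    Cross-run matching over all runs then attempts both within-sample
    transfers (which can be genuine) and cross-sample transfers (which are
    false by construction). The placement exclusion must exceed the matching
    window plus the worst-case replicate RT jitter so that no cross-side
    analyte can ever share an extraction window — the design's guarantee
    that cross-sample transfers are impossible. The returned run→sample map
    identifies the transfer classes.
    """
    if n_per_side < 1 or n_replicates < 1:
        raise ValueError("n_per_side and n_replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rt_hi = gradient_minutes - 2.0
    side_a = random_inventory(
        n_per_side, rng, rt_range=(2.0, rt_hi), rt_exclusion=rt_exclusion
    )
    side_b = random_inventory(
        n_per_side,
        rng,
        rt_range=(2.0, rt_hi),
        existing=side_a,
        rt_exclusion=rt_exclusion,
    )
    runs: list[Run] = []
    ids: list[GPSM] = []
    sample_of_run: dict[str, str] = {}
    truths = []
    for sample, inventory in (("A", side_a), ("B", side_b)):
        for r in range(n_replicates):
            jittered = [
                dataclasses.replace(
                    item,
                    rt=float(item.rt + rng.normal(0.0, rt_jitter)),
                    area=float(item.area * np.exp(rng.normal(0.0, area_jitter))),
                )
                for item in inventory
            ]
            spec = SimSpec(
                inventory=jittered,
                gradient_minutes=gradient_minutes,
                ms1_interval_s=ms1_interval_s,
                id_probability=id_probability,
                seed=seed * 10 + len(runs) + 1,
                **spec_kwargs,
            )
            run_id = f"sample{sample}_rep{r + 1}"
            run, run_ids, truth = simulate_run(spec, run_id=run_id)
            runs.append(run)
            ids.extend(run_ids)
            sample_of_run[run_id] = sample
            truth["sample"] = sample
            truths.append(truth)
    return runs, ids, sample_of_run, pd.concat(truths, ignore_index=True)


def make_replicates(
    n: int,
    n_runs: int = 2,
    seed: int = 0,
    id_probability: float = 0.8,
    rt_jitter: float = 0.3,
    area_jitter: float = 0.10,
    **spec_kwargs,
) -> tuple[list[Run], list[GPSM], pd.DataFrame]:
    """Replicate runs sharing one inventory, with jittered RT and area.

    The shared-inventory design provides the positive pairs (same analyte in
    several runs) and, through the per-run identification lottery, the
    missing cells that cross-run matching fills; it is also the training-data
    design for the matching model.
    """
    rng = np.random.default_rng(seed)
    base = random_inventory(n, rng)
    runs, all_ids, truths = [], [], []
    for r in range(n_runs):
        inv = []
        for item in base:
            inv.append(
                dataclasses.replace(
                    item,
                    rt=float(item.rt + rng.normal(0.0, rt_jitter)),
                    area=float(
                        item.area * np.exp(rng.normal(0.0, area_jitter))
                    ),
                )
            )
        spec = SimSpec(
            inventory=inv,
            id_probability=id_probability,
            seed=seed * 10 + r,
            **spec_kwargs,
        )
        run, ids, truth = simulate_run(spec, run_id=f"rep{r + 1}")
        runs.append(run)
        all_ids.extend(ids)
        truths.append(truth)
    return runs, all_ids, pd.concat(truths, ignore_index=True)


def make_replicate_pair(n: int, seed: int = 0, **kwargs):
    """Two replicate runs sharing one inventory (see make_replicates)."""
    return make_replicates(n, n_runs=2, seed=seed, **kwargs)


def make_mir_benchmark(
    n_present: int = 5,
    n_absent: int = 5,
    n_background: int = 20,
    sa_rt_shift: float = -0.8,
    fwhm: float = 0.2,
    ms1_interval_s: float = 1.0,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[Run, list[GPSM], list[GlycanStructure], pd.DataFrame]:
    """A spike-in benchmark run for in-run glycoform matching.

    ``n_present + n_absent`` anchor glycopeptides carrying the neutral
    biantennary H(5)N(4) glycan are identified; for the first ``n_present``
    anchors the mono-sialylated glycoform is actually present, eluting at the
    anchor RT plus the per-SA shift. A high-mannose background is added; those
    glycans fail the LacNAc screen and generate no candidates. Returns the
    run, the identifications, the glycan-structure database and a truth table
    flagging which candidate glycoforms are truly present.
    """
    rng = np.random.default_rng(seed)
    n_anchor = n_present + n_absent
    anchors = random_inventory(
        n_anchor, rng, fwhm=fwhm, rt_range=(4.0, 16.0), rt_exclusion=3.0
    )
    inventory: list[InventoryItem] = []
    truth_rows = []
    for i, anchor in enumerate(anchors):
        anchor = dataclasses.replace(
            anchor,
            glycan={"Hex": 5, "HexNAc": 4},
            structure=BIANTENNARY_0SA,
            identify=True,
        )
        inventory.append(anchor)
        present = i < n_present
        if present:
            inventory.append(
                dataclasses.replace(
                    anchor,
                    glycan={"Hex": 5, "HexNAc": 4, "NeuAc": 1},
                    structure=BIANTENNARY_1SA,
                    rt=anchor.rt + sa_rt_shift,
                    area=anchor.area * float(rng.uniform(0.5, 1.0)),
                    identify=False,
                )
            )
        truth_rows.append(
            {
                "peptide": anchor.peptide,
                "charge": anchor.charge,
                "glycan_structure": BIANTENNARY_1SA,
                "delta_sa": 1,
                "present": present,
            }
        )
    background = random_inventory(
        n_background, rng, fwhm=fwhm, existing=inventory, rt_exclusion=3.0
    )
    hm_structures = [GlycanStructure.parse(s) for s in HIGH_MANNOSE]
    for j, item in enumerate(background):
        hm = hm_structures[j % len(hm_structures)]
        inventory.append(
            dataclasses.replace(
                item,
                glycan=dict(hm.composition),
                structure=hm.canonical,
                identify=True,
            )
        )
    spec = SimSpec(
        inventory=inventory,
        ms1_interval_s=ms1_interval_s,
        seed=seed + 1,
        **spec_kwargs,
    )
    run, ids, _ = simulate_run(spec, run_id="mir_benchmark")
    db = [
        GlycanStructure.parse(s)
        for s in (BIANTENNARY_0SA, BIANTENNARY_1SA, BIANTENNARY_2SA, *HIGH_MANNOSE)
    ]
    return run, ids, db, pd.DataFrame(truth_rows)


def make_labeled_run(
    mode: str,
    ratios: dict[str, float],
    n: int = 15,
    seed: int = 0,
    **spec_kwargs,
) -> tuple[Run, list[GPSM], pd.DataFrame]:
    """A SILAC channel-pair run or a TMT run with reporter-ion MS2 scans.

    SILAC: every inventory item is duplicated at the heavy-label m/z with the
    requested channel area ratio. TMT: one MS2 scan with noise-free reporter
    peaks at the channel ratios is inserted at each item's apex.
    """
    rng = np.random.default_rng(seed)
    if mode == "silac":
        if set(ratios) != {"light", "heavy"}:
            raise ValueError("SILAC ratios must have channels 'light' and 'heavy'")
        base = random_inventory(n, rng, require_residue="K")
        inventory = []
        for item in base:
            k_shift = item.peptide.count("K") * SILAC_LABELS["K6"][1]
            r_shift = item.peptide.count("R") * SILAC_LABELS["R10"][1]
            inventory.append(
                dataclasses.replace(
                    item,
                    area=item.area * ratios["light"],
                    channel="light",
                    identify=True,
                )
            )
            inventory.append(
                dataclasses.replace(
                    item,
                    area=item.area * ratios["heavy"],
                    mass_offset=k_shift + r_shift,
                    channel="heavy",
                    identify=False,
                )
            )
        spec = SimSpec(inventory=inventory, seed=seed + 1, **spec_kwargs)
        return simulate_run(spec, run_id="silac")
    if mode == "tmt":
        if set(ratios) - set(TMT6_REPORTERS):
            raise ValueError(
                f"unknown TMT channels {sorted(set(ratios) - set(TMT6_REPORTERS))}"
            )
        base = random_inventory(n, rng)
        spec = SimSpec(
            inventory=[
                dataclasses.replace(item, identify=True) for item in base
            ],
            seed=seed + 1,
            **spec_kwargs,
        )
        run, ids, truth = simulate_run(spec, run_id="tmt")
        id_by_pep = {g.peptide: g for g in ids}
        ms2_scans = []
        for k, item in enumerate(base):
            i = run.nearest_ms1_index(item.rt)
            parent = run.ms1_scans[i]
            mzs = np.array([TMT6_REPORTERS[c] for c in sorted(ratios)])
            intens = np.array(
                [item.area * ratios[c] for c in sorted(ratios)]
            )
            order = np.argsort(mzs)
            g = id_by_pep.get(item.peptide)
            ms2_scans.append(
                Scan(
                    scan_id=f"tmt.ms2.{k + 1}",
                    ms_level=2,
                    rt=parent.rt + 1e-4,
                    mz=mzs[order],
                    intensity=intens[order],
                    precursor=(
                        g.precursor_mz if g else 0.0,
                        item.charge,
                        parent.scan_id,
                    ),
                )
            )
            if g is not None:
                g.spectrum_ref = f"tmt.ms2.{k + 1}"
        run = Run(run_id=run.run_id, scans=run.scans + ms2_scans)
        return run, ids, truth
    raise ValueError(f"unknown labeling mode {mode!r}")
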