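"""Quantitation modes (label-free, SILAC, TMT) and level-wise merging.

SILAC channels are quantified at MS1 by building one evidence per channel at
the label-shifted precursor m/z and recording each channel's chromatogram
area, with the evidence-matching model's light/heavy similarity attached when
a trained model is supplied. TMT channels are quantified by picking reporter
ion peaks in MS2 scans. Merging aggregates spectrum intensities by summation
into six levels: spectra, modification, site, protein, glycan occupancy and
site occupancy.
"""

from __future__ import annotations

import dataclasses
import math
import warnings

import pandas as pd

from .evidence import build_evidence, pick_peak
from .io import format_glycan_composition
from .matchnet import MatchModel, _gpsm_pattern, matching_score
from .model import GPSM, QuantRecord, Run, Scan

MERGE_LEVELS = (
    "spectra",
    "modification",
    "site",
    "protein",
    "glycan_occupancy",
    "site_occupancy",
)


def silac_channel_shift(peptide: str, labels: dict[str, float]) -> float:
    """Total label mass shift of a channel: per-residue shift × residue count."""
    return sum(peptide.count(res) * shift for res, shift in labels.items())


def quant_silac(
    run: Run,
    gpsm: GPSM,
    channels: dict[str, dict[str, float]],
    model: MatchModel | None = None,
    tol_ppm: float = 20.0,
) -> list[QuantRecord]:
    """Quantify one GPSM per SILAC channel at MS1.

    ``channels`` maps channel name to a residue→mass-shift table, e.g.
    ``{"light": {}, "heavy": {"K": 6.020129, "R": 6.020129}}``. When the
    peptide carries no labelled residue the channels are indistinguishable and
    only the first channel is quantified (with a warning).
    """
    shifts = {
        name: silac_channel_shift(gpsm.peptide, table)
        for name, table in channels.items()
    }
    if len(set(shifts.values())) < len(shifts):
        warnings.warn(
            f"peptide {gpsm.peptide!r} has no labelled residue; "
            "quantifying a single channel"
        )
        first = next(iter(channels))
        shifts = {first: shifts[first]}
    pattern = _gpsm_pattern(gpsm)
    trigger = run.ms1_index_at_or_before(gpsm.rt)
    evidences = {}
    for name, shift in shifts.items():
        p = dataclasses.replace(pattern, mz=pattern.mz + shift / gpsm.charge)
        evidences[name] = build_evidence(run, p, trigger, tol_ppm, ref=name)
    score = None
    if model is not None and model.trained and len(evidences) >= 2:
        pair = [ev for ev in evidences.values() if ev is not None][:2]
        if len(pair) == 2:
            score = matching_score(model, pair[0], pair[1])
        else:
            score = 0.0
    records = []
    for name, ev in evidences.items():
        # a channel with no mono-trace signal is missing, not zero
        if ev is None or ev.mono_area <= 0:
            continue
        records.append(
            QuantRecord(
                gpsm=gpsm,
                run_id=run.run_id,
                channel=name,
                intensity=ev.mono_area,
                origin="identified",
                score=score,
            )
        )
    return records


def quant_tmt(
    ms2: Scan,
    channels: dict[str, float],
    tol_ppm: float = 10.0,
) -> dict[str, float]:
    """Reporter-ion intensity per channel in one MS2 scan (0 when absent)."""
    if ms2.ms_level != 2:
        raise ValueError("TMT reporter picking requires an MS2 scan")
    out = {
        name: pick_peak(ms2, mz, tol_ppm) for name, mz in channels.items()
    }
    if not any(out.values()):
        warnings.warn(f"scan {ms2.scan_id}: no reporter peaks found")
    return out


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _level_key(rec: QuantRecord, level: str) -> tuple:
    g = rec.gpsm
    glycan = format_glycan_composition(g.glycan_composition)
    if level == "spectra":
        return (g.run_id, g.spectrum_ref, g.peptide, glycan, g.charge)
    if level == "modification":
        mods = ";".join(f"{p},{n}" for p, n, _ in sorted(g.modifications))
        return (g.peptide, mods, glycan)
    if level in ("site", "glycan_occupancy"):
        if not g.glycosite:
            raise ValueError(
                f"record {g.spectrum_ref!r} lacks a glycosite at level={level}"
            )
        return (g.protein, g.glycosite, glycan)
    if level == "site_occupancy":
        if not g.glycosite:
            raise ValueError(
                f"record {g.spectrum_ref!r} lacks a glycosite at level={level}"
            )
        return (g.protein, glycan, g.glycosite)
    if level == "protein":
        return (g.protein,)
    raise ValueError(f"unknown merge level {level!r}")


def merge(records: list[QuantRecord], level: str) -> pd.DataFrame:
    """Aggregate accepted records at a level into a key × channel frame.

    Cell values are correctly-rounded sums (math.fsum) of the contributing
    spectrum intensities, so totals are conserved across levels. Missing cells
    are NaN, distinct from a detected zero.
    """
    if level not in MERGE_LEVELS:
        raise ValueError(f"unknown merge level {level!r}")
    cells: dict[tuple, dict[str, list[float]]] = {}
    channels: list[str] = []
    for rec in records:
        if not rec.accepted:
            continue
        key = _level_key(rec, level)
        cells.setdefault(key, {}).setdefault(rec.channel, []).append(rec.intensity)
        if rec.channel not in channels:
            channels.append(rec.channel)
    channels.sort()
    rows = {
        key: {
            ch: math.fsum(values) for ch, values in per_channel.items()
        }
        for key, per_channel in sorted(cells.items(), key=lambda kv: tuple(map(str, kv[0])))
    }
    frame = pd.DataFrame.from_dict(rows, orient="index", columns=channels)
    frame.index.name = level
    return frame
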