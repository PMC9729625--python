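"""Pipeline orchestration: configuration, staging, logging.

The pipeline follows three steps — reading identifications, extracting
evidences, and mode-specific quantitation processing (with cross-run matching
under FQR control and optional in-run glycoform matching) — before merging
intensities into the six ``.list`` tables.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import shutil
from dataclasses import dataclass, field

import yaml

from . import io as gio
from . import mbr as mbr_mod
from . import mir as mir_mod
from .matchnet import MatchModel, _gpsm_evidence
from .model import QuantMatrix, QuantRecord

logger = logging.getLogger("glyquant")


@dataclass
class Config:
    mode: str = "labelfree"  # labelfree | silac | tmt
    dialect: str = "native"
    tol_ppm: float = 20.0
    max_isotopes: int = 6
    mbr_window: float = 2.0  # minutes each side
    alpha: float = 0.01  # FQR level
    mir_enabled: bool = False
    glycan_db: str | None = None
    sa_rt_shift: float | None = None  # minutes per sialic acid; None = estimate
    mir_window: float = 1.0  # half-width around the expected candidate RT
    model_path: str | None = None
    seed: int = 0
    out_dir: str = "glyquant_out"
    runs: list[str] = field(default_factory=list)  # mzML paths
    ids: list[str] = field(default_factory=list)  # identification tables

    @classmethod
    def from_yaml(cls, path: str) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def validate(self) -> None:
        if self.mode not in ("labelfree", "silac", "tmt"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.tol_ppm <= 0 or self.mbr_window <= 0:
            raise ValueError("tol_ppm and mbr_window must be positive")
        if not (0 < self.alpha <= 1):
            raise ValueError("alpha must be in (0, 1]")
        if self.mir_enabled and not self.glycan_db:
            raise ValueError("MIR requires a glycan structure database")


def run_pipeline(
    config: Config,
    runs=None,
    ids=None,
    model: MatchModel | None = None,
) -> QuantMatrix:
    """Execute the label-free pipeline and write the six ``.list`` tables.

    ``runs`` and ``ids`` may be passed in-memory (lists of Run / GPSM); when
    absent they are loaded from the paths in the config. Any stage failure
    aborts with a stage-named error and removes partial outputs.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    try:
        return _run_stages(config, runs, ids, model)
    except Exception as exc:
        shutil.rmtree(config.out_dir, ignore_errors=True)
        raise RuntimeError(f"pipeline failed: {exc}") from exc


def _run_stages(config: Config, runs, ids, model: MatchModel | None) -> QuantMatrix:
    # stage 1: read
    if runs is None:
        runs = [gio.read_mzml(p) for p in config.runs]
    if ids is None:
        ids = []
        for p in config.ids:
            ids.extend(gio.parse_identifications(p, config.dialect))
    logger.info("stage 1: %d runs, %d identifications", len(runs), len(ids))
    run_by_id = {r.run_id: r for r in runs}

    # stage 2+3: evidence extraction and quantitation
    if model is None and config.model_path:
        model = MatchModel.load(config.model_path)
    if len(runs) >= 2 and model is not None:
        results, matrix = mbr_mod.match_between_runs(
            runs,
            ids,
            model,
            window=config.mbr_window,
            alpha=config.alpha,
            tol_ppm=config.tol_ppm,
            seed=config.seed,
        )
        n_accepted = sum(r.accepted for r in results)
        logger.info(
            "stage 3: %d match attempts, %d accepted at FQR<=%g",
            len(results),
            n_accepted,
            config.alpha,
        )
    else:
        matrix = QuantMatrix(columns=[r.run_id for r in runs])
        for g in ids:
            if g.run_id not in run_by_id:
                continue
            ev = _gpsm_evidence(run_by_id[g.run_id], g, config.tol_ppm)
            if ev is not None:
                matrix.add(
                    QuantRecord(
                        gpsm=g,
                        run_id=g.run_id,
                        channel=g.run_id,
                        intensity=ev.mono_area,
                        origin="identified",
                    )
                )

    if config.mir_enabled:
        db = mir_mod.load_glycan_db(config.glycan_db)
        db = mir_mod.screen_lacnac(db)
        subnets = mir_mod.build_subnets(db) if db else []
        shift = config.sa_rt_shift
        if shift is None:
            shift = mir_mod.estimate_sa_rt_shift(ids) or 0.0
        quantified_keys = {
            (rec.gpsm.glycopeptide_key, rec.run_id) for rec in matrix.records
        }
        n_mir = 0
        for g in ids:
            if g.run_id not in run_by_id:
                continue
            for cand in mir_mod.candidates_for(g, subnets, shift):
                key = (
                    (cand.anchor.peptide, tuple(sorted(cand.composition.items())),
                     cand.anchor.charge),
                    g.run_id,
                )
                hit = mir_mod.mir_search(
                    run_by_id[g.run_id],
                    cand,
                    (cand.expected_rt - config.mir_window,
                     cand.expected_rt + config.mir_window),
                    tol_ppm=config.tol_ppm,
                )
                if hit is None:
                    continue
                mir_gpsm = dataclasses.replace(
                    g,
                    spectrum_ref=f"mir:{g.spectrum_ref}:{cand.glycan.canonical}",
                    glycan_composition=dict(cand.composition),
                    glycan_structure=cand.glycan.canonical,
                    precursor_mz=cand.precursor_mz,
                    precursor_mass=(cand.precursor_mz - 1.007276466) * g.charge,
                    rt=float(hit.evidence.apex_rt),
                )
                if (mir_gpsm.glycopeptide_key, g.run_id) in quantified_keys:
                    continue  # MIR never overwrites identification-backed values
                matrix.add(
                    QuantRecord(
                        gpsm=mir_gpsm,
                        run_id=g.run_id,
                        channel=g.run_id,
                        intensity=hit.intensity,
                        origin="mir",
                        score=hit.score_mir,
                    )
                )
                n_mir += 1
        logger.info("stage 3b: %d glycoforms added via MIR", n_mir)

    gio.write_list_tables(matrix, config.out_dir)
    logger.info(
        "wrote %d records across %d runs to %s",
        len(matrix.records),
        len(runs),
        config.out_dir,
    )
    return matrix
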