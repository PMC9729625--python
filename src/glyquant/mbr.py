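"""Match Between Runs with FQR control.

For every glycopeptide identified in at least one run but missing in another,
candidate evidences with the same precursor mass are enumerated inside a
±2-minute retention window of the reference (one per local maximum of the
monoisotopic trace), each is scored against the reference evidence by the
matching model, and the best-scoring candidate is kept. Decoy precursors
(+10 Da) run through the identical path; the pooled target+decoy scores feed
the Gaussian-mixture FQR fit, and only matches above the FQR threshold fill
the quantitation matrix.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from . import fqr as fqr_mod
from .evidence import build_evidence
from .matchnet import MatchModel, _gpsm_evidence, _gpsm_pattern, matching_score
from .model import GPSM, Evidence, IsotopePattern, MatchResult, QuantMatrix, QuantRecord, Run

DEFAULT_WINDOW = 2.0  # minutes, each side
DEFAULT_ALPHA = 0.01
#: matches scoring at or below this are "no plausible candidate": rejected
#: outright and kept out of the mixture fit
SCORE_FLOOR = 0.01
#: minimum informative decoy scores required to fit the mixture; below this
#: the empirical decoy maximum is the acceptance threshold
MIN_DECOYS_FOR_FIT = 10


def _logit(s: np.ndarray) -> np.ndarray:
    s = np.clip(s, 1e-6, 1.0 - 1e-6)
    return np.log(s / (1.0 - s))


def _expit(z: float) -> float:
    return float(1.0 / (1.0 + np.exp(-z)))


def enumerate_candidates(
    run: Run,
    pattern: IsotopePattern,
    rt_center: float,
    window: float = DEFAULT_WINDOW,
    tol_ppm: float = 20.0,
) -> list[Evidence]:
    """Candidate evidences inside the half-open window [center−w, center+w).

    One candidate per local maximum of the monoisotopic trace; each is built
    by the standard evidence extension with that local apex as the trigger
    scan. Candidates sharing an identical scan span are deduplicated.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    ms1 = run.ms1_scans
    idx = [
        i
        for i, s in enumerate(ms1)
        if rt_center - window <= s.rt < rt_center + window
    ]
    if not idx:
        return []
    from .evidence import pick_peak

    # one context scan beyond each edge so window clipping cannot turn a
    # rising flank into a spurious local maximum
    lo = max(idx[0] - 1, 0)
    hi = min(idx[-1] + 1, len(ms1) - 1)
    context = list(range(lo, hi + 1))
    mono_ctx = np.array([pick_peak(ms1[i], pattern.mz[0], tol_ppm) for i in context])
    offset = idx[0] - lo
    candidates: list[Evidence] = []
    seen_spans: set[tuple[float, float]] = set()
    for k in range(len(idx)):
        c = k + offset
        if mono_ctx[c] <= 0:
            continue
        left_ok = c == 0 or mono_ctx[c] >= mono_ctx[c - 1]
        right_ok = c == len(context) - 1 or mono_ctx[c] > mono_ctx[c + 1]
        if not (left_ok and right_ok):
            continue
        ev = build_evidence(run, pattern, idx[k], tol_ppm)
        if ev is None:
            continue
        span = (ev.rt_start, ev.rt_end)
        if span in seen_spans:
            continue
        seen_spans.add(span)
        candidates.append(ev)
    return candidates


def _best_match(
    model: MatchModel,
    reference: Evidence,
    candidates: list[Evidence],
) -> tuple[Evidence | None, float]:
    best, best_score = None, -1.0
    for cand in candidates:
        score = matching_score(model, reference, cand)
        if score > best_score:
            best, best_score = cand, score
    if best is None:
        return None, 0.0
    return best, best_score


def match_between_runs(
    runs: list[Run],
    ids: list[GPSM],
    model: MatchModel,
    window: float = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    tol_ppm: float = 20.0,
    seed: int = 0,
) -> tuple[list[MatchResult], QuantMatrix]:
    """Fill missing (glycopeptide, run) cells by evidence matching.

    Returns all match attempts (targets and decoys, each with its score and
    accept flag) and the quantitation matrix holding identification-backed
    records plus FQR-accepted transferred records. Unaccepted cells stay
    missing.
    """
    if model is None or not model.trained:
        raise ValueError("match_between_runs requires a trained model")
    run_by_id = {r.run_id: r for r in runs}
    matrix = QuantMatrix(columns=[r.run_id for r in runs])

    by_key: dict[tuple, dict[str, GPSM]] = {}
    for g in ids:
        if g.run_id in run_by_id:
            by_key.setdefault(g.glycopeptide_key, {})[g.run_id] = g

    reference_evidence: dict[tuple, Evidence | None] = {}
    for key, per_run in by_key.items():
        for run_id, g in per_run.items():
            ev = _gpsm_evidence(run_by_id[run_id], g, tol_ppm)
            reference_evidence[(key, run_id)] = ev
            if ev is not None:
                matrix.add(
                    QuantRecord(
                        gpsm=g,
                        run_id=run_id,
                        channel=run_id,
                        intensity=ev.mono_area,
                        origin="identified",
                    )
                )

    def attempt(g: GPSM, ref_ev: Evidence, target_run: Run, pattern) -> MatchResult:
        cands = enumerate_candidates(target_run, pattern, g.rt, window, tol_ppm)
        best, score = _best_match(model, ref_ev, cands)
        return MatchResult(
            glycopeptide_key=g.glycopeptide_key,
            source_run=g.run_id,
            target_run=target_run.run_id,
            reference=ref_ev,
            best_candidate=best,
            score=score,
            is_decoy=g.is_decoy,
        )

    results: list[MatchResult] = []
    for key, per_run in by_key.items():
        # reference = the identified run with the most intense evidence
        with_ev = [
            (run_id, g, reference_evidence[(key, run_id)])
            for run_id, g in per_run.items()
            if reference_evidence[(key, run_id)] is not None
        ]
        if not with_ev:
            continue
        src_id, src_g, src_ev = max(with_ev, key=lambda t: t[2].mono_area)
        pattern = src_ev.pattern or _gpsm_pattern(src_g)
        decoy_g = fqr_mod.make_decoys([src_g])[0]
        decoy_shift = fqr_mod.DECOY_MASS_SHIFT / src_g.charge
        decoy_pattern = dataclasses.replace(pattern, mz=pattern.mz + decoy_shift)
        for target_id, target_run in run_by_id.items():
            if target_id in per_run:
                continue
            result = attempt(src_g, src_ev, target_run, pattern)
            if result.best_candidate is not None:
                results.append(result)
            # identical enumerate/score path for the +10 Da decoy precursor:
            # same reference evidence, candidates at the shifted mass, so a
            # decoy match is a true reference paired with necessarily false
            # candidate evidence
            decoy_result = attempt(decoy_g, src_ev, target_run, decoy_pattern)
            if decoy_result.best_candidate is not None:
                results.append(decoy_result)

    scored = [r for r in results if r.best_candidate is not None]
    # near-zero scores mean "no plausible candidate at all"; they are
    # rejected outright and excluded from the mixture fit, which would
    # otherwise collapse its false component onto the point mass at 0.
    # The fit runs on the logit of the score: softmax outputs saturate
    # near 0 and 1, and on that open scale the two populations are far
    # closer to Gaussian; the threshold maps back monotonically.
    informative = np.array(
        [r.score for r in scored if r.score > SCORE_FLOOR]
    )
    target_scores = np.array(
        [r.score for r in scored if not r.is_decoy and r.score > SCORE_FLOOR]
    )
    decoy_scores = np.array(
        [r.score for r in scored if r.is_decoy and r.score > SCORE_FLOOR]
    )

    if len(decoy_scores) < MIN_DECOYS_FOR_FIT:
        # the decoy channel barely clears the floor: neither the mixture nor
        # a counting estimate is determined at any alpha, so accept targets
        # scoring above every informative decoy
        threshold = float(max(decoy_scores.max(initial=0.0), SCORE_FLOOR))
    else:
        # empirical target-decoy bound: smallest score t at which the
        # estimated false fraction above t (decoys>t over targets>t, with
        # the conservative +1 decoy pseudocount) stays within alpha
        tda_threshold = None
        for t in np.sort(target_scores):
            n_targets = (target_scores > t).sum()
            n_decoys = (decoy_scores > t).sum()
            if n_targets > 0 and (n_decoys + 1) / n_targets <= alpha:
                tda_threshold = float(t)
                break

        # parametric mixture threshold, fitted on logit scores
        gmm_threshold = None
        if len(np.unique(np.round(informative, 12))) >= 2:
            z = _logit(informative)
            params = fqr_mod.kmeans_init(z, seed=seed)
            params = fqr_mod.em_fit(z, params)
            z_threshold = fqr_mod.threshold_for_fqr(params, z, alpha)
            if z_threshold is not None:
                gmm_threshold = max(_expit(z_threshold), SCORE_FLOOR)

        candidates_t = [
            t for t in (tda_threshold, gmm_threshold) if t is not None
        ]
        threshold = max(candidates_t) if candidates_t else None
    for r in scored:
        r.accepted = threshold is not None and r.score > threshold and not r.is_decoy
        if r.accepted:
            g = next(
                g for g in ids if g.glycopeptide_key == r.glycopeptide_key
            )
            transferred = dataclasses.replace(
                g, run_id=r.source_run, is_decoy=False
            )
            matrix.add(
                QuantRecord(
                    gpsm=transferred,
                    run_id=r.target_run,
                    channel=r.target_run,
                    intensity=r.best_candidate.mono_area,
                    origin="mbr",
                    score=r.score,
                    accepted=True,
                )
            )
    return results, matrix
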