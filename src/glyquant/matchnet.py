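"""Learned evidence-matching model.

Each evidence is rasterized to a fixed K×L image (K isotopologue traces
resampled onto L uniform retention-time bins, max-normalized), encoded by a
residual network into a 512-dimensional embedding, and a pair of embeddings is
reduced to a 16-vector that is combined with 10 classical chromatographic pair
features before a softmax head yields the match probability in [0, 1].

Training pairs are mined from label-free data: positives are the same
glycopeptide identified in two runs with |ΔRT| < 2 min and a relative
intensity difference < 30%; negatives pair an identified glycopeptide with a
random evidence in another run at a 4-minute RT offset and a different
precursor mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import nn
from .evidence import build_evidence
from .isotope import cosine_similarity, emass_pattern, glycopeptide_formula
from .model import GPSM, Evidence, Run

DEFAULT_K = 6  # isotopologue rows in the raster
DEFAULT_L = 64  # retention-time bins in the raster
EMBED_DIM = 512

FEATURE_NAMES = [
    "iso_cosine",  # cosine of apex-scan isotope envelopes
    "delta_rt",  # |ΔRT| of apices, minutes
    "trace_corr",  # Pearson correlation of resampled mono traces
    "log_area_ratio",  # log10 ratio of mono areas
    "fwhm_ratio",  # ratio of FWHMs (min/max)
    "ppm_diff",  # ppm difference of theoretical mono m/z
    "n_coisotopes",  # number of co-detected isotopes
    "apex_ratio",  # ratio of apex intensities (min/max)
    "rt_overlap",  # peak-boundary overlap fraction in RT
    "snr_diff",  # signal-to-baseline ratio difference (log10)
]


def rasterize_evidence(e: Evidence, K: int = DEFAULT_K, L: int = DEFAULT_L) -> np.ndarray:
    """Resample an evidence onto a fixed K×L grid, max-normalized to [0, 1]."""
    grid = np.zeros((K, L))
    n_iso, n_scans = e.intensities.shape
    if n_scans == 1:
        grid[: min(K, n_iso), :] = e.intensities[:K, [0]]
    else:
        bins = np.linspace(e.rt_start, e.rt_end, L)
        for i in range(min(K, n_iso)):
            grid[i] = np.interp(bins, e.rt, e.intensities[i])
    peak = grid.max()
    if peak > 0:
        grid /= peak
    return grid


def _resampled_mono(e: Evidence, L: int) -> np.ndarray:
    if len(e.rt) == 1:
        return np.full(L, e.intensities[0, 0])
    bins = np.linspace(e.rt_start, e.rt_end, L)
    return np.interp(bins, e.rt, e.intensities[0])


def _fwhm(e: Evidence, L: int = DEFAULT_L) -> float:
    trace = _resampled_mono(e, L)
    peak = trace.max()
    if peak <= 0:
        return 0.0
    above = trace >= 0.5 * peak
    span = e.rt_end - e.rt_start
    return float(above.sum() / L * max(span, 1e-6))


def classical_features(a: Evidence, b: Evidence, L: int = DEFAULT_L) -> np.ndarray:
    """The 10 classical pair features, in the order of FEATURE_NAMES."""
    eps = 1e-9
    env_a, env_b = a.apex_envelope(), b.apex_envelope()
    n = min(len(env_a), len(env_b))
    f_cos = cosine_similarity(env_a[:n], env_b[:n])
    f_drt = abs(a.apex_rt - b.apex_rt)
    ta, tb = _resampled_mono(a, L), _resampled_mono(b, L)
    if ta.std() > 0 and tb.std() > 0:
        f_corr = float(np.corrcoef(ta, tb)[0, 1])
    else:
        f_corr = 0.0
    f_area = float(np.log10((a.mono_area + eps) / (b.mono_area + eps)))
    wa, wb = _fwhm(a), _fwhm(b)
    f_fwhm = float(min(wa, wb) / max(wa, wb, eps))
    if a.pattern is not None and b.pattern is not None:
        mza, mzb = a.pattern.mz[0], b.pattern.mz[0]
        f_ppm = float(abs(mza - mzb) / mza * 1e6)
    else:
        f_ppm = 0.0
    det_a = a.intensities[:n].max(axis=1) > 0
    det_b = b.intensities[:n].max(axis=1) > 0
    f_codet = float(np.sum(det_a & det_b))
    pa = a.intensities.sum(axis=0)[a.apex_scan]
    pb = b.intensities.sum(axis=0)[b.apex_scan]
    f_apex = float(min(pa, pb) / max(pa, pb, eps))
    lo = max(a.rt_start, b.rt_start)
    hi = min(a.rt_end, b.rt_end)
    union = max(a.rt_end, b.rt_end) - min(a.rt_start, b.rt_start)
    f_overlap = float(max(hi - lo, 0.0) / max(union, eps))

    def _snr(e: Evidence) -> float:
        profile = e.intensities.sum(axis=0)
        base = np.median(profile)
        return float(np.log10((profile.max() + eps) / (base + eps)))

    f_snr = abs(_snr(a) - _snr(b))
    return np.array(
        [f_cos, f_drt, f_corr, f_area, f_fwhm, f_ppm, f_codet, f_apex, f_overlap, f_snr]
    )


@dataclass
class TrainingPair:
    evidence_a: Evidence
    evidence_b: Evidence
    label: int  # 1 = positive (match), 0 = negative


class MatchModel:
    """Residual encoder + pair heads producing a match score in [0, 1].

    The encoder maps the flattened K×L raster through a dense stem to the
    512-dimensional embedding and two residual blocks. Pair head A reduces the
    concatenated 1024-vector to 16 dimensions through one hidden layer of 128;
    head B combines those 16 values with the 10 standardized classical
    features into the 2-class softmax whose "match" probability is the score.
    """

    def __init__(self, K: int = DEFAULT_K, L: int = DEFAULT_L, seed: int = 0):
        self.K, self.L = K, L
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.stem = nn.Dense(rng, K * L, EMBED_DIM)
        self.block1 = nn.ResidualBlock(rng, EMBED_DIM)
        self.block2 = nn.ResidualBlock(rng, EMBED_DIM)
        self.head_a1 = nn.Dense(rng, 2 * EMBED_DIM, 128)
        self.head_a2 = nn.Dense(rng, 128, 16)
        self.head_b = nn.Dense(rng, 16 + len(FEATURE_NAMES), 2)
        self.feature_mean = np.zeros(len(FEATURE_NAMES))
        self.feature_std = np.ones(len(FEATURE_NAMES))
        self.trained = False

    # -- plumbing ----------------------------------------------------------
    def _layers(self):
        return [self.stem, self.block1, self.block2, self.head_a1, self.head_a2, self.head_b]

    def _params(self):
        return [p for layer in self._layers() for p in layer.params()]

    def _zero_grad(self):
        for layer in self._layers():
            layer.zero_grad()

    # -- forward/backward --------------------------------------------------
    def _encode(self, x: np.ndarray):
        h, c_stem = self.stem.forward(x)
        a = nn.relu(h)
        r1, c1 = self.block1.forward(a)
        r2, c2 = self.block2.forward(r1)
        return r2, (c_stem, h, c1, c2)

    def _encode_backward(self, grad: np.ndarray, cache) -> None:
        c_stem, h, c1, c2 = cache
        g = self.block2.backward(grad, c2)
        g = self.block1.backward(g, c1)
        g = g * (h > 0)
        self.stem.backward(g, c_stem)

    def _forward(self, xa: np.ndarray, xb: np.ndarray, feats: np.ndarray):
        ea, ca = self._encode(xa)
        eb, cb = self._encode(xb)
        pair = np.concatenate([ea, eb], axis=1)
        h1, ch1 = self.head_a1.forward(pair)
        a1 = nn.relu(h1)
        v16, ch2 = self.head_a2.forward(a1)
        fz = (feats - self.feature_mean) / self.feature_std
        combined = np.concatenate([v16, fz], axis=1)
        logits, ch3 = self.head_b.forward(combined)
        probs = nn.softmax(logits)
        cache = (ca, cb, ch1, h1, ch2, ch3)
        return probs, cache

    def _backward(self, probs: np.ndarray, labels: np.ndarray, cache) -> None:
        ca, cb, ch1, h1, ch2, ch3 = cache
        B = len(labels)
        dlogits = probs.copy()
        dlogits[np.arange(B), labels] -= 1.0
        dlogits /= B
        dcombined = self.head_b.backward(dlogits, ch3)
        dv16 = dcombined[:, :16]
        da1 = self.head_a2.backward(dv16, ch2)
        dh1 = da1 * (h1 > 0)
        dpair = self.head_a1.backward(dh1, ch1)
        self._encode_backward(dpair[:, :EMBED_DIM], ca)
        self._encode_backward(dpair[:, EMBED_DIM:], cb)

    # -- public API --------------------------------------------------------
    def score_batch(
        self, images_a: np.ndarray, images_b: np.ndarray, feats: np.ndarray
    ) -> np.ndarray:
        if not self.trained:
            raise RuntimeError("match model has not been trained")
        xa = images_a.reshape(len(images_a), -1)
        xb = images_b.reshape(len(images_b), -1)
        probs, _ = self._forward(xa, xb, feats)
        return probs[:, 1]

    def save(self, path: str) -> None:
        arrays = {"K": self.K, "L": self.L, "seed": self.seed,
                  "feature_mean": self.feature_mean,
                  "feature_std": self.feature_std,
                  "feature_names": np.array(FEATURE_NAMES)}
        for i, layer in enumerate(self._layers()):
            for j, (p, _) in enumerate(layer.params()):
                arrays[f"w_{i}_{j}"] = p
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path: str) -> "MatchModel":
        data = np.load(path, allow_pickle=False)
        model = cls(K=int(data["K"]), L=int(data["L"]), seed=int(data["seed"]))
        for i, layer in enumerate(model._layers()):
            for j, (p, _) in enumerate(layer.params()):
                p[...] = data[f"w_{i}_{j}"]
        model.feature_mean = data["feature_mean"]
        model.feature_std = data["feature_std"]
        model.trained = True
        return model


def matching_score(model: MatchModel, a: Evidence, b: Evidence) -> float:
    """Match score of an evidence pair; reference evidence goes first."""
    xa = rasterize_evidence(a, model.K, model.L)[None]
    xb = rasterize_evidence(b, model.K, model.L)[None]
    feats = classical_features(a, b, model.L)[None]
    return float(model.score_batch(xa, xb, feats)[0])


# ---------------------------------------------------------------------------
# training-pair mining
# ---------------------------------------------------------------------------

POSITIVE_RT_LIMIT = 2.0  # minutes
POSITIVE_INTENSITY_LIMIT = 0.30  # relative difference
NEGATIVE_RT_OFFSET = 4.0  # minutes


def _gpsm_pattern(g: GPSM, n_peaks: int = DEFAULT_K):
    formula = glycopeptide_formula(g.peptide, g.modifications, g.glycan_composition)
    return emass_pattern(formula, g.charge, n_peaks)


def _gpsm_evidence(
    run: Run, g: GPSM, tol_ppm: float, n_peaks: int = DEFAULT_K
) -> Evidence | None:
    pattern = _gpsm_pattern(g, n_peaks)
    trigger = run.ms1_index_at_or_before(g.rt)
    return build_evidence(run, pattern, trigger, tol_ppm, ref=g.spectrum_ref)


def mine_training_pairs(
    runs: list[Run],
    ids: list[GPSM],
    n_pos: int = 3000,
    n_neg: int = 3000,
    seed: int = 0,
    tol_ppm: float = 20.0,
) -> list[TrainingPair]:
    """Mine positive and negative evidence pairs from label-free runs.

    Returns up to n_pos positives and n_neg negatives (with a warning when
    fewer qualify), sampled reproducibly under the seed.
    """
    if len(runs) < 2:
        raise ValueError("label-free pair mining needs at least 2 runs")
    rng = np.random.default_rng(seed)
    run_by_id = {r.run_id: r for r in runs}
    ids = [g for g in ids if g.run_id in run_by_id]
    by_key: dict[tuple, dict[str, GPSM]] = {}
    for g in ids:
        by_key.setdefault(g.glycopeptide_key, {})[g.run_id] = g

    evidence_cache: dict[tuple[str, str], Evidence | None] = {}

    def get_evidence(g: GPSM) -> Evidence | None:
        key = (g.run_id, g.spectrum_ref)
        if key not in evidence_cache:
            evidence_cache[key] = _gpsm_evidence(run_by_id[g.run_id], g, tol_ppm)
        return evidence_cache[key]

    # positives: same glycopeptide in two runs, close RT, similar intensity
    pos_candidates = []
    for key, per_run in by_key.items():
        run_ids = sorted(per_run)
        for i in range(len(run_ids)):
            for j in range(i + 1, len(run_ids)):
                ga, gb = per_run[run_ids[i]], per_run[run_ids[j]]
                if abs(ga.rt - gb.rt) < POSITIVE_RT_LIMIT:
                    pos_candidates.append((ga, gb))
    rng.shuffle(pos_candidates)
    positives: list[TrainingPair] = []
    for ga, gb in pos_candidates:
        if len(positives) >= n_pos:
            break
        ea, eb = get_evidence(ga), get_evidence(gb)
        if ea is None or eb is None:
            continue
        ia, ib = ea.mono_area, eb.mono_area
        if max(ia, ib) <= 0:
            continue
        if abs(ia - ib) / max(ia, ib) < POSITIVE_INTENSITY_LIMIT:
            positives.append(TrainingPair(ea, eb, 1))

    # negatives: identified glycopeptide vs a random evidence at ±4 min with a
    # different precursor mass in a run where it was not identified
    ids_by_run: dict[str, list[GPSM]] = {}
    for g in ids:
        ids_by_run.setdefault(g.run_id, []).append(g)
    neg_candidates = []
    for key, per_run in by_key.items():
        for run_id, g in per_run.items():
            for other_id in run_by_id:
                if other_id != run_id and other_id not in per_run:
                    neg_candidates.append((g, other_id))
    if not neg_candidates:  # fall back to cross-run pairs of different peptides
        for g in ids:
            for other_id in run_by_id:
                if other_id != g.run_id:
                    neg_candidates.append((g, other_id))
    rng.shuffle(neg_candidates)
    negatives: list[TrainingPair] = []
    for g, other_id in neg_candidates:
        if len(negatives) >= n_neg:
            break
        other_run = run_by_id[other_id]
        ea = get_evidence(g)
        if ea is None:
            continue
        directions = [-1.0, 1.0] if rng.random() < 0.5 else [1.0, -1.0]
        for direction in directions:
            if len(negatives) >= n_neg:
                break
            target_rt = g.rt + direction * NEGATIVE_RT_OFFSET
            # random different-mass glycopeptides eluting near the offset RT
            pool = [
                h
                for h in ids_by_run.get(other_id, [])
                if abs(h.precursor_mass - g.precursor_mass) > 1.0
                and abs(h.rt - target_rt) <= 1.0
            ]
            rng.shuffle(pool)
            for h in pool[:2]:
                pattern = _gpsm_pattern(h)
                trigger = other_run.ms1_index_at_or_before(target_rt)
                eb = build_evidence(
                    other_run, pattern, trigger, tol_ppm, ref=h.spectrum_ref
                )
                if eb is None:
                    continue
                negatives.append(TrainingPair(ea, eb, 0))
                if len(negatives) >= n_neg:
                    break

    if len(positives) < n_pos or len(negatives) < n_neg:
        warnings.warn(
            f"mined {len(positives)} positive / {len(negatives)} negative pairs "
            f"(requested {n_pos}/{n_neg})"
        )
    return positives + negatives


def train(
    pairs: list[TrainingPair],
    K: int = DEFAULT_K,
    L: int = DEFAULT_L,
    epochs: int = 30,
    batch_size: int = 64,
    lr: float = 1e-3,
    seed: int = 0,
    log: list[dict] | None = None,
) -> MatchModel:
    """Train the matching model on mined pairs with softmax cross-entropy."""
    labels = np.array([p.label for p in pairs])
    if len(set(labels.tolist())) < 2:
        raise ValueError("training needs both positive and negative pairs")
    model = MatchModel(K=K, L=L, seed=seed)
    xa = np.stack([rasterize_evidence(p.evidence_a, K, L).ravel() for p in pairs])
    xb = np.stack([rasterize_evidence(p.evidence_b, K, L).ravel() for p in pairs])
    feats = np.stack([classical_features(p.evidence_a, p.evidence_b, L) for p in pairs])
    model.feature_mean = feats.mean(axis=0)
    model.feature_std = np.maximum(feats.std(axis=0), 1e-6)
    fz_input = feats  # standardized inside _forward

    rng = np.random.default_rng(seed + 1)
    optimizer = nn.Adam(model._params(), lr=lr)
    n = len(pairs)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            model._zero_grad()
            probs, cache = model._forward(xa[idx], xb[idx], fz_input[idx])
            loss = nn.cross_entropy(probs, labels[idx])
            model._backward(probs, labels[idx], cache)
            optimizer.step()
            epoch_loss += loss
            n_batches += 1
        if log is not None:
            log.append({"epoch": epoch, "loss": epoch_loss / max(n_batches, 1)})
    model.trained = True
    return model
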