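"""Evidence rasterization, pair features, mining rules and model training."""

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from glyquant.evidence import build_evidence
from glyquant.isotope import cosine_similarity
from glyquant.matchnet import (
    MatchModel,
    TrainingPair,
    classical_features,
    matching_score,
    mine_training_pairs,
    rasterize_evidence,
    train,
)
from glyquant.model import Evidence, IsotopePattern

from conftest import make_profile_run

PATTERN = IsotopePattern(
    mz=np.array([800.0, 800.5, 801.0]), abundance=np.array([1.0, 0.7, 0.3]), charge=2
)


def _evidence(rt, intensities, ref="e"):
    intensities = np.atleast_2d(np.asarray(intensities, dtype=float))
    profile = intensities.sum(axis=0)
    return Evidence(
        ref=ref,
        rt=np.asarray(rt, dtype=float),
        intensities=intensities,
        apex_scan=int(np.argmax(profile)),
        trigger_scan=0,
        mono_area=float(np.trapezoid(intensities[0], rt)),
        pattern=PATTERN,
    )


class TestRasterize:
    def test_uniform_grid_is_identity_after_normalization(self):
        rt = np.linspace(0, 1, 8)
        trace = np.array([0, 1, 4, 8, 6, 3, 1, 0], dtype=float)
        e = _evidence(rt, trace)
        img = rasterize_evidence(e, K=6, L=8)
        assert np.allclose(img[0], trace / trace.max())
        assert np.all(img[1:] == 0)

    def test_intensity_scaling_invariance(self):
        rt = np.linspace(0, 1, 5)
        e1 = _evidence(rt, [1, 5, 9, 4, 1])
        e2 = _evidence(rt, [5, 25, 45, 20, 5])
        assert np.allclose(
            rasterize_evidence(e1, 6, 16), rasterize_evidence(e2, 6, 16)
        )

    def test_linear_interpolation_matches_hand_computation(self):
        rt = np.array([0.0, 1.0, 2.0])
        rows = np.array([[0.0, 10.0, 0.0], [2.0, 4.0, 6.0]])
        e = _evidence(rt, rows)
        img = rasterize_evidence(e, K=2, L=6)
        bins = np.linspace(0.0, 2.0, 6)
        expected = np.vstack(
            [np.interp(bins, rt, rows[0]), np.interp(bins, rt, rows[1])]
        )
        assert np.allclose(img, expected / expected.max())


class TestClassicalFeatures:
    def test_self_pair_has_zero_rt_distance_and_unit_cosine(self):
        rt = np.linspace(10, 11, 12)
        rows = np.vstack([np.hamming(12) * s for s in (1.0, 0.7, 0.3)])
        e = _evidence(rt, rows)
        feats = classical_features(e, e)
        assert feats[1] == 0.0  # ΔRT
        assert feats[0] == pytest.approx(1.0)  # envelope cosine
        assert feats[2] == pytest.approx(1.0)  # trace correlation

    def test_apex_rt_distance_is_subtraction(self):
        rt_a = np.linspace(9.5, 10.5, 11)
        rt_b = rt_a + 1.5
        shape = np.hamming(11)
        a, b = _evidence(rt_a, shape), _evidence(rt_b, shape)
        assert classical_features(a, b)[1] == pytest.approx(1.5)

    def test_envelope_cosine_agrees_with_isotope_module(self):
        rt = np.linspace(0, 1, 9)
        rows_a = np.vstack([np.hamming(9) * s for s in (1.0, 0.5, 0.2)])
        rows_b = np.vstack([np.hamming(9) * s for s in (1.0, 0.8, 0.1)])
        a, b = _evidence(rt, rows_a), _evidence(rt, rows_b)
        expected = cosine_similarity(a.apex_envelope(), b.apex_envelope())
        assert classical_features(a, b)[0] == pytest.approx(expected)


class TestMiningRules:
    def test_positive_rule_rt_and_intensity_limits(self, trained_model_bundle):
        _, pairs, runs, ids = trained_model_bundle
        positives = [p for p in pairs if p.label == 1]
        assert positives
        for p in positives[:50]:
            assert abs(p.evidence_a.apex_rt - p.evidence_b.apex_rt) < 2.5
            ia, ib = p.evidence_a.mono_area, p.evidence_b.mono_area
            assert abs(ia - ib) / max(ia, ib) < 0.3 + 0.2  # rule on id'd areas

    def test_negative_pairs_sit_near_four_minute_offset(self, trained_model_bundle):
        _, pairs, _, _ = trained_model_bundle
        negatives = [p for p in pairs if p.label == 0]
        assert negatives
        offsets = [
            abs(p.evidence_a.apex_rt - p.evidence_b.apex_rt) for p in negatives
        ]
        assert np.median(offsets) > 2.0

    def test_requires_two_runs(self):
        with pytest.raises(ValueError):
            mine_training_pairs([], [], 10, 10)

    def test_default_pair_budget_is_three_thousand_each(self):
        import inspect

        sig = inspect.signature(mine_training_pairs)
        assert sig.parameters["n_pos"].default == 3000
        assert sig.parameters["n_neg"].default == 3000


class TestTraining:
    def test_scores_lie_in_unit_interval_and_are_reproducible(
        self, trained_model_bundle
    ):
        model, pairs, _, _ = trained_model_bundle
        for p in pairs[:10]:
            s1 = matching_score(model, p.evidence_a, p.evidence_b)
            s2 = matching_score(model, p.evidence_a, p.evidence_b)
            assert 0.0 <= s1 <= 1.0
            assert s1 == s2

    def test_untrained_model_refuses_to_score(self):
        model = MatchModel(seed=0)
        rt = np.linspace(0, 1, 5)
        e = _evidence(rt, [1, 4, 9, 4, 1])
        with pytest.raises(RuntimeError):
            matching_score(model, e, e)

    def test_training_is_deterministic_under_seed(self, trained_model_bundle):
        _, pairs, _, _ = trained_model_bundle
        subset = pairs[:40] + pairs[-40:]
        log1: list[dict] = []
        log2: list[dict] = []
        m1 = train(subset, epochs=2, seed=5, log=log1)
        m2 = train(subset, epochs=2, seed=5, log=log2)
        assert log1[-1]["loss"] == log2[-1]["loss"]
        assert np.array_equal(m1.stem.W, m2.stem.W)

    def test_single_class_input_raises(self, trained_model_bundle):
        _, pairs, _, _ = trained_model_bundle
        positives = [p for p in pairs if p.label == 1][:10]
        with pytest.raises(ValueError):
            train(positives, epochs=1)

    def test_heldout_separation_on_clean_synthetic_pairs(self, trained_model_bundle):
        """Held-out positives outscore negatives (accuracy > 0.9, MW p < 0.01)."""
        model, _, _, _ = trained_model_bundle
        from glyquant.matchnet import mine_training_pairs as mine
        from glyquant.synthio import make_replicates

        runs, ids, _ = make_replicates(100, n_runs=3, seed=555)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            heldout = mine(runs, ids, n_pos=60, n_neg=60, seed=556)
        pos = [
            matching_score(model, p.evidence_a, p.evidence_b)
            for p in heldout
            if p.label == 1
        ]
        neg = [
            matching_score(model, p.evidence_a, p.evidence_b)
            for p in heldout
            if p.label == 0
        ]
        assert len(pos) >= 30 and len(neg) >= 30
        correct = sum(s > 0.5 for s in pos) + sum(s < 0.5 for s in neg)
        assert correct / (len(pos) + len(neg)) > 0.9
        assert mannwhitneyu(pos, neg, alternative="greater").pvalue < 0.01

    def test_save_load_roundtrip_preserves_scores(
        self, trained_model_bundle, tmp_path
    ):
        model, pairs, _, _ = trained_model_bundle
        path = tmp_path / "model.npz"
        model.save(str(path))
        back = MatchModel.load(str(path))
        for p in pairs[:5]:
            assert matching_score(model, p.evidence_a, p.evidence_b) == pytest.approx(
                matching_score(back, p.evidence_a, p.evidence_b), abs=1e-12
            )
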