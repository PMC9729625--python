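"""SILAC/TMT quantitation and the level-wise merge aggregation."""

import math
import warnings

import numpy as np
import pytest

from glyquant.constants import SILAC_LABELS, TMT6_REPORTERS
from glyquant.model import QuantRecord, Scan
from glyquant.quantmerge import (
    merge,
    quant_silac,
    quant_tmt,
    silac_channel_shift,
)
from glyquant.synthio import make_labeled_run

from conftest import simple_gpsm

SILAC_CHANNELS = {
    "light": {},
    "heavy": {"K": SILAC_LABELS["K6"][1], "R": SILAC_LABELS["R10"][1]},
}


class TestSilac:
    def test_heavy_mz_shift_arithmetic(self):
        # one K with the +6.020129 label at charge 2 → +3.0100645 m/z
        shift = silac_channel_shift("AJSSEK", {"K": SILAC_LABELS["K6"][1]})
        assert shift / 2 == pytest.approx(3.0100645)

    def test_one_to_one_ratio_recovered(self):
        run, ids, _ = make_labeled_run("silac", {"light": 1.0, "heavy": 1.0}, n=8, seed=2)
        ratios = []
        for g in ids:
            recs = {r.channel: r.intensity for r in quant_silac(run, g, SILAC_CHANNELS)}
            if recs.get("heavy"):
                ratios.append(recs["light"] / recs["heavy"])
        assert len(ratios) >= 6
        assert np.median(ratios) == pytest.approx(1.0, rel=0.02)

    def test_unlabelable_peptide_warns_and_gives_single_channel(self):
        g = simple_gpsm(peptide="AJSSEG")  # no K or R
        run, _, _ = make_labeled_run("silac", {"light": 1.0, "heavy": 1.0}, n=4, seed=3)
        with pytest.warns(UserWarning):
            recs = quant_silac(run, g, SILAC_CHANNELS)
        assert {r.channel for r in recs} <= {"light"}

    def test_absent_heavy_channel_is_missing(self):
        run, ids, _ = make_labeled_run("silac", {"light": 1.0, "heavy": 1.0}, n=6, seed=4)
        g = ids[0]
        # shift the heavy channel to an empty m/z region by a fake huge label
        channels = {"light": {}, "heavy": {"K": 137.0, "R": 137.0}}
        recs = {r.channel: r.intensity for r in quant_silac(run, g, channels)}
        assert "light" in recs
        assert "heavy" not in recs


class TestTmt:
    def test_reporter_peaks_picked_per_channel(self):
        mzs = sorted(TMT6_REPORTERS[c] for c in ("126", "127"))
        scan = Scan(
            scan_id="ms2",
            ms_level=2,
            rt=5.0,
            mz=np.array(mzs),
            intensity=np.array([1000.0, 2000.0]),
        )
        out = quant_tmt(scan, {c: TMT6_REPORTERS[c] for c in ("126", "127")})
        assert out["126"] == 1000.0
        assert out["127"] == 2000.0

    def test_ratio_exact_before_noise(self):
        run, ids, _ = make_labeled_run("tmt", {"126": 1.0, "127": 2.0}, n=5, seed=3)
        ms2 = [s for s in run.scans if s.ms_level == 2][0]
        out = quant_tmt(ms2, {c: TMT6_REPORTERS[c] for c in ("126", "127")})
        assert out["127"] / out["126"] == pytest.approx(2.0)

    def test_glycopeptide_value_sums_over_gpsms(self):
        g = simple_gpsm()
        records = [
            QuantRecord(gpsm=g, run_id="r", channel="126", intensity=10.0),
            QuantRecord(gpsm=g, run_id="r", channel="126", intensity=20.0),
        ]
        frame = merge(records, "modification")
        assert frame["126"].iloc[0] == pytest.approx(30.0)

    def test_no_reporters_warns_and_returns_zeros(self):
        scan = Scan(
            scan_id="ms2", ms_level=2, rt=5.0,
            mz=np.array([500.0]), intensity=np.array([1.0]),
        )
        with pytest.warns(UserWarning):
            out = quant_tmt(scan, {c: TMT6_REPORTERS[c] for c in ("126", "127")})
        assert set(out.values()) == {0.0}

    def test_ms1_scan_is_rejected(self):
        scan = Scan(
            scan_id="ms1", ms_level=1, rt=5.0,
            mz=np.array([500.0]), intensity=np.array([1.0]),
        )
        with pytest.raises(ValueError):
            quant_tmt(scan, {"126": TMT6_REPORTERS["126"]})


class TestMerge:
    def _records(self, rng=None, n=20):
        rng = rng or np.random.default_rng(0)
        records = []
        for i in range(n):
            g = simple_gpsm(
                spectrum_ref=f"s{i}",
                peptide=["AJSSEK", "GJK"][i % 2],
                glycosite=2,
                protein=f"P{i % 3}",
            )
            records.append(
                QuantRecord(
                    gpsm=g,
                    run_id=f"run{i % 2 + 1}",
                    channel=f"run{i % 2 + 1}",
                    intensity=float(rng.integers(1, 1000)),
                )
            )
        return records

    def test_site_level_sums_same_key(self):
        g = simple_gpsm(protein="P1", glycosite=2)
        recs = [
            QuantRecord(gpsm=g, run_id="r1", channel="r1", intensity=10.0),
            QuantRecord(
                gpsm=simple_gpsm(spectrum_ref="s2", protein="P1", glycosite=2),
                run_id="r1", channel="r1", intensity=20.0,
            ),
        ]
        frame = merge(recs, "site")
        assert frame["r1"].iloc[0] == pytest.approx(30.0)

    def test_total_intensity_conserved_across_levels(self):
        records = self._records()
        totals = {}
        for level in ("spectra", "modification", "site", "protein"):
            frame = merge(records, level)
            totals[level] = math.fsum(
                v for v in frame.to_numpy().ravel() if not np.isnan(v)
            )
        assert len(set(totals.values())) == 1  # exact conservation

    def test_permutation_invariance(self):
        records = self._records()
        a = merge(records, "protein")
        b = merge(records[::-1], "protein")
        assert a.equals(b)

    def test_missing_glycosite_error_names_record(self):
        g = simple_gpsm(spectrum_ref="sX", glycosite=0)
        rec = QuantRecord(gpsm=g, run_id="r", channel="r", intensity=1.0)
        with pytest.raises(ValueError, match="sX"):
            merge([rec], "site")

    def test_unknown_level_raises(self):
        with pytest.raises(ValueError):
            merge([], "peptidoform")
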