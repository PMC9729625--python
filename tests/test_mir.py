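"""Glycan canonical structures, subnets, and in-run glycoform matching."""

import numpy as np
import pytest

from glyquant.constants import MONOSACCHARIDE_MASSES
from glyquant.mir import (
    GlycanStructure,
    build_subnets,
    candidates_for,
    estimate_sa_rt_shift,
    mir_search,
    screen_lacnac,
    strip_sialic,
)
from glyquant.synthio import (
    BIANTENNARY_0SA,
    BIANTENNARY_1SA,
    BIANTENNARY_2SA,
    HIGH_MANNOSE,
    make_mir_benchmark,
)

from conftest import simple_gpsm


class TestCanonicalStructures:
    def test_parse_and_composition(self):
        g = GlycanStructure.parse(BIANTENNARY_2SA)
        assert g.composition == {"HexNAc": 4, "Hex": 5, "NeuAc": 2}
        assert g.n_sialic == 2

    def test_canonicalization_orders_siblings(self):
        a = GlycanStructure.parse("(N(H)(F))")
        b = GlycanStructure.parse("(N(F)(H))")
        assert a.canonical == b.canonical

    @pytest.mark.parametrize("bad", ["", "(X)", "(N(H)", "N(H)"])
    def test_malformed_strings_raise(self, bad):
        with pytest.raises((ValueError, IndexError)):
            GlycanStructure.parse(bad)


class TestStripSialic:
    def test_no_sialic_is_identity(self):
        g = GlycanStructure.parse(BIANTENNARY_0SA)
        assert strip_sialic(g) == g.canonical

    def test_biantennary_2sa_reduces_to_backbone(self):
        g = GlycanStructure.parse(BIANTENNARY_2SA)
        assert strip_sialic(g) == GlycanStructure.parse(BIANTENNARY_0SA).canonical

    def test_structures_differing_only_in_sa_share_output(self):
        assert strip_sialic(GlycanStructure.parse(BIANTENNARY_1SA)) == strip_sialic(
            GlycanStructure.parse(BIANTENNARY_2SA)
        )

    def test_sialic_with_children_is_structural_error(self):
        g = GlycanStructure.parse("(N(A(H)))")
        with pytest.raises(ValueError, match="sialic"):
            strip_sialic(g)


class TestSubnets:
    def _db(self):
        return [
            GlycanStructure.parse(s)
            for s in (
                BIANTENNARY_0SA,
                BIANTENNARY_1SA,
                BIANTENNARY_2SA,
                HIGH_MANNOSE[0],
                HIGH_MANNOSE[1],
                HIGH_MANNOSE[2],
            )
        ]

    def test_groups_by_infrastructure(self):
        subnets = build_subnets(self._db())
        sizes = sorted(len(s.members) for s in subnets)
        assert sizes == [1, 1, 1, 3]

    def test_partition_is_disjoint_and_complete(self):
        db = self._db()
        subnets = build_subnets(db)
        seen = [m.canonical for s in subnets for m in s.members]
        assert sorted(seen) == sorted(g.canonical for g in db)

    def test_order_invariance(self):
        db = self._db()
        a = build_subnets(db)
        b = build_subnets(db[::-1])
        assert [s.infrastructure for s in a] == [s.infrastructure for s in b]

    def test_singleton_database(self):
        (subnet,) = build_subnets([GlycanStructure.parse(BIANTENNARY_0SA)])
        assert len(subnet.members) == 1


class TestLacNAcScreen:
    def test_oligomannose_excluded_biantennary_kept(self):
        db = [
            GlycanStructure.parse(HIGH_MANNOSE[2]),  # H(9)N(2)
            GlycanStructure.parse(BIANTENNARY_0SA),
        ]
        kept = screen_lacnac(db)
        assert [g.canonical for g in kept] == [
            GlycanStructure.parse(BIANTENNARY_0SA).canonical
        ]

    def test_empty_database(self):
        assert screen_lacnac([]) == []


class TestSaRtShift:
    def _pair(self, rt0, rt2, peptide="AJSSEK", ref="a"):
        base = dict(peptide=peptide, glycosite=2, charge=2)
        g0 = simple_gpsm(
            spectrum_ref=f"{ref}0", rt=rt0,
            glycan_composition={"Hex": 5, "HexNAc": 4}, **base,
        )
        g2 = simple_gpsm(
            spectrum_ref=f"{ref}2", rt=rt2,
            glycan_composition={"Hex": 5, "HexNAc": 4, "NeuAc": 2}, **base,
        )
        return g0, g2

    def test_median_over_pairs(self):
        # three peptide groups with per-SA shifts −1.2, −1.0, −1.4 → median −1.2
        ids = []
        for i, (peptide, drt) in enumerate(
            [("AJSSEK", -1.2), ("GJTTLK", -1.0), ("WJDDAR", -1.4)]
        ):
            rt0 = 10.0 + 10 * i
            ids += self._pair(rt0, rt0 + 2 * drt, peptide=peptide, ref=f"p{i}_")
        assert estimate_sa_rt_shift(ids) == pytest.approx(-1.2)

    def test_single_pair_returns_its_value(self):
        g0, g2 = self._pair(10.0, 8.0)
        assert estimate_sa_rt_shift([g0, g2]) == pytest.approx(-1.0)

    def test_no_pairs_warns_and_returns_none(self):
        g = simple_gpsm()
        with pytest.warns(UserWarning):
            assert estimate_sa_rt_shift([g]) is None


class TestCandidates:
    def _subnets(self):
        return build_subnets(
            [
                GlycanStructure.parse(s)
                for s in (BIANTENNARY_0SA, BIANTENNARY_1SA, BIANTENNARY_2SA)
            ]
        )

    def test_mass_shifts_are_neuac_multiples(self):
        g = simple_gpsm(
            glycan_composition={"Hex": 5, "HexNAc": 4},
            glycan_structure=BIANTENNARY_0SA,
            charge=2,
            rt=10.0,
        )
        cands = candidates_for(g, self._subnets(), sa_rt_shift=-0.8)
        assert len(cands) == 2
        neuac = MONOSACCHARIDE_MASSES["NeuAc"]
        shifts = sorted(c.precursor_mz - g.precursor_mz for c in cands)
        assert shifts[0] == pytest.approx(neuac / 2)
        assert shifts[1] == pytest.approx(2 * neuac / 2)
        by_dsa = {c.delta_sa: c for c in cands}
        assert by_dsa[1].expected_rt == pytest.approx(10.0 - 0.8)
        assert by_dsa[2].expected_rt == pytest.approx(10.0 - 1.6)

    def test_composition_fallback_without_structure(self):
        g = simple_gpsm(glycan_composition={"Hex": 5, "HexNAc": 4})
        cands = candidates_for(g, self._subnets())
        assert {c.delta_sa for c in cands} == {1, 2}

    def test_glycan_absent_from_db_gives_empty(self):
        g = simple_gpsm(glycan_composition={"Hex": 9, "HexNAc": 2})
        assert candidates_for(g, self._subnets()) == []

    def test_candidates_differ_from_anchor_only_in_sialic_acids(self):
        g = simple_gpsm(glycan_composition={"Hex": 5, "HexNAc": 4})
        for c in candidates_for(g, self._subnets()):
            stripped = {
                k: v for k, v in c.composition.items() if k not in ("NeuAc", "NeuGc")
            }
            assert stripped == g.glycan_composition


class TestMirSearch:
    def test_benchmark_recovers_present_rejects_absent(self):
        """Spiked glycoforms score above 5; unspiked ones return nothing."""
        run, ids, db, truth = make_mir_benchmark(seed=5)
        subnets = build_subnets(screen_lacnac(db))
        scores = {}
        for _, row in truth.iterrows():
            anchor = next(
                g
                for g in ids
                if g.peptide == row.peptide
                and g.glycan_composition == {"Hex": 5, "HexNAc": 4}
            )
            (cand,) = [
                c
                for c in candidates_for(anchor, subnets, sa_rt_shift=-0.8)
                if c.delta_sa == 1
            ]
            hit = mir_search(run, cand, (cand.expected_rt - 1, cand.expected_rt + 1))
            scores[row.peptide] = (row.present, hit)
        present = [h for flag, h in scores.values() if flag]
        absent = [h for flag, h in scores.values() if not flag]
        assert all(h is not None and h.score_mir > 5 for h in present)
        assert all(h is None or h.score_mir < min(p.score_mir for p in present)
                   for h in absent)

    def test_score_is_sum_of_retained_similarities(self):
        run, ids, db, truth = make_mir_benchmark(seed=6)
        subnets = build_subnets(screen_lacnac(db))
        row = truth[truth.present].iloc[0]
        anchor = next(
            g for g in ids
            if g.peptide == row.peptide
            and g.glycan_composition == {"Hex": 5, "HexNAc": 4}
        )
        (cand,) = [
            c for c in candidates_for(anchor, subnets, sa_rt_shift=-0.8)
            if c.delta_sa == 1
        ]
        hit = mir_search(run, cand, (cand.expected_rt - 1, cand.expected_rt + 1))
        assert hit.score_mir == pytest.approx(hit.per_scan_sim.sum())
        assert np.all(hit.per_scan_sim >= 0.9)
        # bounded by the number of retained scans
        assert 0.9 * len(hit.per_scan_sim) <= hit.score_mir <= len(hit.per_scan_sim)

    def test_gate_rejects_top1_below_threshold(self):
        run, ids, db, truth = make_mir_benchmark(seed=7)
        subnets = build_subnets(screen_lacnac(db))
        row = truth[~truth.present].iloc[0]
        anchor = next(
            g for g in ids
            if g.peptide == row.peptide
            and g.glycan_composition == {"Hex": 5, "HexNAc": 4}
        )
        (cand,) = [
            c for c in candidates_for(anchor, subnets, sa_rt_shift=-0.8)
            if c.delta_sa == 1
        ]
        hit = mir_search(run, cand, (cand.expected_rt - 1, cand.expected_rt + 1))
        assert hit is None
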