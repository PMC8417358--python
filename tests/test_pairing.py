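"""Insert-size model, dual coordinates, pair scoring and SAM output."""

import random

import numpy as np
import pysam
import pytest

from panrescue.pairing import (
    Candidate,
    InsertSizeModel,
    dual_coordinates,
    emit_sam,
    estimate_isize,
    filter_original_best,
    score_pairings,
)
from panrescue.realign import SingleEndAlignment
from panrescue.signals import OrigAlignment, SignalRead
from panrescue.svref import SVRecord


class TestInsertSizeModel:
    def test_recovers_normal_moments(self):
        rng = np.random.default_rng(1)
        model = estimate_isize(rng.normal(400, 50, 10_000).astype(int))
        assert abs(model.mean - 400) < 5
        assert abs(model.sd - 50) < 5

    def test_degenerate_identical_isizes(self):
        model = estimate_isize([300] * 500)
        assert model.sd == 0
        lo, hi = model.interval
        assert (lo, hi) == (299.0, 301.0)  # +/- 1 bp floor

    def test_fallback_on_small_sample(self):
        model = estimate_isize([400] * 10, fallback=(350.0, 42.0))
        assert (model.mean, model.sd) == (350.0, 42.0)


class TestDualCoordinates:
    DEL = SVRecord("d", "c", 1000, 1500, "DEL", 500)
    INS = SVRecord("i", "c", 1000, 1000, "INS", 120, "A" * 120)

    def test_upstream_mate_keeps_single_coordinate(self):
        assert dual_coordinates(800, self.DEL) == [(800, False)]

    def test_downstream_of_deletion_offers_shifted_value(self):
        assert dual_coordinates(1600, self.DEL) == [(1600, False), (1100, True)]

    def test_downstream_of_insertion_shifts_the_other_way(self):
        assert dual_coordinates(1200, self.INS) == [(1200, False), (1320, True)]


def _pan(anchor_id, start, score, strand="+", read_len=100):
    aln = SingleEndAlignment(anchor_id, start, start + read_len, 0, read_len,
                             strand, f"{read_len}M", score, 0)
    return Candidate("pan", score, strand, aln=aln)


def _orig(contig, pos, score, strand="+", flag=None, isize=300):
    if flag is None:
        flag = 0x1 | (0x10 if strand == "-" else 0x20)
    o = OrigAlignment(contig, pos, flag, score, "100M", 60, isize, 0)
    return Candidate("orig", score, strand, orig=o)


@pytest.fixture()
def model():
    return InsertSizeModel(300.0, 30.0)


class TestScorePairings:
    def test_proper_pair_gets_bonus(self, toy_svref, model):
        r1 = [_pan(0, 100, 100.0, "+")]
        r2 = [_pan(0, 300, 100.0, "-")]
        best = score_pairings(r1, r2, model, toy_svref, bonus=50)
        assert best.score == 250.0 and best.proper

    def test_improper_pair_no_bonus(self, toy_svref, model):
        r1 = [_pan(0, 100, 100.0, "+")]
        r2 = [_pan(0, 3000, 100.0, "-")]  # isize far outside the window
        best = score_pairings(r1, r2, model, toy_svref, bonus=50)
        assert best.score == 200.0 and not best.proper

    def test_bonus_can_overturn_raw_score_ranking(self, toy_svref, model):
        r1 = [_pan(0, 2000, 100.0, "+"), _pan(0, 100, 90.0, "+")]
        r2 = [_pan(0, 300, 80.0, "-")]  # proper only with the 90-score end
        best = score_pairings(r1, r2, model, toy_svref, bonus=50)
        assert best.score == 220.0
        assert best.c1.aln.anchor_start == 100

    def test_same_strand_never_proper(self, toy_svref, model):
        r1 = [_pan(0, 100, 100.0, "+")]
        r2 = [_pan(0, 300, 100.0, "+")]
        assert not score_pairings(r1, r2, model, toy_svref).proper

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_over_all_combinations(self, toy_svref, model, seed):
        rng = random.Random(seed)
        def cands(n):
            out = []
            for _ in range(n):
                if rng.random() < 0.7:
                    out.append(_pan(rng.randint(0, 1), rng.randrange(0, 400),
                                    rng.randint(40, 150), rng.choice("+-")))
                else:
                    out.append(_orig("c", rng.randrange(1, 2800),
                                     rng.randint(40, 150), rng.choice("+-")))
            return out
        r1, r2 = cands(rng.randint(1, 13)), cands(rng.randint(1, 13))
        best = score_pairings(r1, r2, model, toy_svref, bonus=50)
        from panrescue.pairing import _proper
        oracle = max(
            c1.score + c2.score + (50 if _proper(c1, c2, model, toy_svref) else 0)
            for c1 in r1 for c2 in r2
        )
        assert best.score == pytest.approx(oracle)

    def test_bonus_irrelevant_when_nothing_is_proper(self, toy_svref, model):
        r1 = [_pan(0, 100, 100.0, "+"), _pan(1, 50, 90.0, "+")]
        r2 = [_pan(1, 500, 80.0, "+")]  # same strand: never proper
        a = score_pairings(r1, r2, model, toy_svref, bonus=0)
        b = score_pairings(r1, r2, model, toy_svref, bonus=500)
        assert a.score == b.score

    def test_single_end_when_mate_list_empty(self, toy_svref, model):
        best = score_pairings([_pan(0, 100, 88.0)], [], model, toy_svref)
        assert best.score == 88.0 and best.c2 is None
        assert score_pairings([], [], model, toy_svref) is None


class TestFilterOriginalBest:
    def test_kept_when_realignment_strictly_wins(self, toy_svref, model):
        r1 = [_pan(0, 100, 120.0, "+"), _orig("c", 800, 100.0, "+")]
        r2 = [_pan(0, 300, 130.0, "-"), _orig("c", 1000, 120.0, "-")]
        best = filter_original_best(r1, r2, model, toy_svref, bonus=50)
        assert best is not None
        assert best.c1.source == "pan" and best.c2.source == "pan"

    def test_tie_with_original_is_unmapped(self, toy_svref, model):
        # pan pair and original pair both reach 250 (both proper)
        r1 = [_pan(0, 100, 100.0, "+"), _orig("c", 755, 100.0, "+", isize=290)]
        r2 = [_pan(0, 300, 100.0, "-"), _orig("c", 945, 100.0, "-", isize=-290)]
        assert filter_original_best(r1, r2, model, toy_svref, bonus=50) is None

    def test_original_strictly_better_is_unmapped(self, toy_svref, model):
        r1 = [_pan(0, 100, 80.0, "+"), _orig("c", 755, 140.0, "+", isize=290)]
        r2 = [_orig("c", 945, 140.0, "-", isize=-290)]
        assert filter_original_best(r1, r2, model, toy_svref, bonus=50) is None

    def test_no_realignment_at_all_is_unmapped(self, toy_svref, model):
        r1 = [_orig("c", 755, 140.0, "+")]
        r2 = [_orig("c", 945, 140.0, "-")]
        assert filter_original_best(r1, r2, model, toy_svref, bonus=50) is None


class TestEmitSam:
    def _kept(self, toy_svref, model):
        rows = []
        for i, (start, strand, mate) in enumerate(
            [(120, "+", 1), (320, "-", 2), (40, "+", 1)]
        ):
            aln = SingleEndAlignment(i % 2, start, start + 100, 0, 100, strand,
                                     "100M", 100.0, 0)
            cand = Candidate("pan", 100.0, strand, aln=aln)
            from panrescue.pairing import PairScore
            ps = PairScore(200.0, cand, None, True, 50.0)
            sig = SignalRead(f"r{i}", "ACGT" * 25, "I" * 100, mate, None)
            rows.append((sig, aln, ps))
        return rows

    def test_output_parses_and_is_coordinate_sorted(self, toy_svref, model, tmp_path):
        path = tmp_path / "realn.sam"
        emit_sam(self._kept(toy_svref, model), toy_svref, path, seed=9)
        with pysam.AlignmentFile(str(path), "r") as af:
            names = [sq for sq in af.references]
            recs = list(af)
        assert names == [a.name for a in toy_svref.anchors]
        keys = [(r.reference_id, r.reference_start) for r in recs]
        assert keys == sorted(keys)

    def test_za_tag_refers_to_existing_anchor(self, toy_svref, model, tmp_path):
        path = tmp_path / "realn.sam"
        emit_sam(self._kept(toy_svref, model), toy_svref, path)
        with pysam.AlignmentFile(str(path), "r") as af:
            for rec in af:
                za = rec.get_tag("za")
                assert 0 <= za < len(toy_svref.anchors)
                assert rec.reference_name == toy_svref.anchors[za].name
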