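"""Depth/MAPQ filters, greedy assembly, consensus alignment, inference."""

import random

import numpy as np
import pytest

from panrescue import assembly as asm
from panrescue.clustering import ClusterRead, ReadCluster
from panrescue.pairing import PairScore
from panrescue.realign import SingleEndAlignment
from panrescue.signals import OrigAlignment, SignalRead
from panrescue.svref import AnchorSequence, SVRecord, SVReference


def _cluster_read(name, seq, anchor_id, start, score=150.0, mapq=60,
                  orig_score=100.0, mate=1, strand="+"):
    aln = SingleEndAlignment(anchor_id, start, start + len(seq), 0, len(seq),
                             strand, f"{len(seq)}M", score, 0)
    orig = OrigAlignment("c", 1, 0x1, orig_score, "100M", mapq, 300, 0)
    sig = SignalRead(name, seq, "I" * len(seq), mate, orig)
    return ClusterRead(sig, aln, PairScore(score, None, None, True, 0.0))


def _ins_anchor(rng, flank=150, svlen=80):
    up = "".join(rng.choice("ACGT") for _ in range(flank))
    allele = "".join(rng.choice("ACGT") for _ in range(svlen))
    down = "".join(rng.choice("ACGT") for _ in range(flank))
    sv = SVRecord("i", "c", 1000, 1000, "INS", svlen, allele)
    return AnchorSequence(0, sv, up + allele + down, flank, flank)


def _tiling_reads(hap, read_len=60, step=6, prefix="t"):
    starts = list(range(0, len(hap) - read_len + 1, step))
    if starts[-1] != len(hap) - read_len:  # cover the final bases too
        starts.append(len(hap) - read_len)
    return [
        _cluster_read(f"{prefix}{i}", hap[s : s + read_len], 0, s)
        for i, s in enumerate(starts)
    ]


class TestDepthFilter:
    def _cluster(self, n_reads, anchor_len=128):
        rng = random.Random(0)
        seq = "".join(rng.choice("ACGT") for _ in range(anchor_len))
        anchor = AnchorSequence(0, SVRecord("d", "c", 500, 628, "DEL", 128), seq, 64, 64)
        reads = [_cluster_read(f"r{i}", seq[:64], 0, 0, score=100.0 + i)
                 for i in range(n_reads)]
        return ReadCluster(anchor, reads)

    def test_overcovered_block_trimmed_to_limit(self):
        cluster = self._cluster(50)  # block depth 50 at mean 30 -> limit 45
        kept = asm.depth_filter(cluster, mean_depth=30.0)
        assert len(kept) == 45
        # lowest-scoring reads went first
        assert min(r.new_score for r in kept) == 100.0 + 5

    def test_block_under_limit_unchanged(self):
        cluster = self._cluster(40)
        assert len(asm.depth_filter(cluster, mean_depth=30.0)) == 40

    def test_equal_scores_removed_by_name_deterministically(self):
        rng = random.Random(0)
        seq = "".join(rng.choice("ACGT") for _ in range(128))
        anchor = AnchorSequence(0, SVRecord("d", "c", 500, 628, "DEL", 128), seq, 64, 64)
        reads = [_cluster_read(f"r{i:02d}", seq[:64], 0, 0, score=100.0)
                 for i in range(48)]
        kept = asm.depth_filter(ReadCluster(anchor, reads), mean_depth=30.0)
        assert sorted(r.signal.name for r in kept) == [f"r{i:02d}" for i in range(3, 48)]


class TestMapqFilter:
    def _reads(self, n, mapq0_frac, gain):
        reads = []
        for i in range(n):
            mapq = 0 if i < n * mapq0_frac else 60
            reads.append(_cluster_read(f"r{i}", "ACGT" * 20, 0, 0,
                                       score=100.0 + gain, mapq=mapq, orig_score=100.0))
        return reads

    def test_mapq0_cluster_without_score_gain_discarded(self):
        assert not asm.mapq_filter(self._reads(20, 0.9, gain=0))

    def test_mapq0_cluster_with_real_gain_kept(self):
        assert asm.mapq_filter(self._reads(20, 0.9, gain=40))

    def test_mostly_confident_cluster_kept(self):
        assert asm.mapq_filter(self._reads(20, 0.5, gain=0))


class TestAssemble:
    def test_error_free_tiling_reads_reconstruct_haplotype(self):
        rng = random.Random(8)
        anchor = _ins_anchor(rng)
        hap = anchor.seq
        reads = _tiling_reads(hap)
        (cons, *rest) = asm.assemble(reads, anchor, read_length_hint=60)
        assert not rest
        assert cons.contig == hap
        assert len(cons.members) == len(reads)

    def test_noisy_reads_majority_vote(self):
        rng = random.Random(9)
        anchor = _ins_anchor(rng, flank=90, svlen=120)
        hap = anchor.seq  # 300 bp
        reads = []
        for i, start in enumerate(range(0, len(hap) - 60 + 1, 3)):
            seq = list(hap[start : start + 60])
            if rng.random() < 0.6:  # ~1% per-base error overall
                j = rng.randrange(60)
                seq[j] = rng.choice([b for b in "ACGT" if b != seq[j]])
            reads.append(_cluster_read(f"n{i}", "".join(seq), 0, start))
        (cons, *_) = asm.assemble(reads, anchor, read_length_hint=60)
        mism = sum(1 for a, b in zip(cons.contig, hap) if a != b)
        assert len(cons.contig) == len(hap)
        assert mism <= 1

    def test_two_reads_make_no_contig(self):
        rng = random.Random(10)
        anchor = _ins_anchor(rng)
        reads = _tiling_reads(anchor.seq)[:2]
        assert asm.assemble(reads, anchor, read_length_hint=60) == []

    def test_depth_equals_pileup_of_join_positions(self):
        rng = random.Random(11)
        anchor = _ins_anchor(rng)
        reads = _tiling_reads(anchor.seq)
        (cons, *_) = asm.assemble(reads, anchor, read_length_hint=60)
        oracle = np.zeros(len(cons.contig), dtype=int)
        for _i, join in cons.members:
            oracle[max(0, join) : join + 60] += 1
        assert np.array_equal(cons.depth, oracle)


class TestRealignToContig:
    def test_read_with_excess_mismatches_excluded_from_depth(self):
        contig = "ACGTACGTACGTACGTACGTACGTACGT"
        good = contig[:20]
        bad = "TTTTT" + contig[5:20]
        depth = asm.realign_reads_to_contig([good, bad], contig, [0, 0], max_mm=3)
        # the 5-mismatch read is excluded outright; only the clean read counts
        assert depth[:20].tolist() == [1] * 20
        assert depth[20:].tolist() == [0] * 8

    def test_empty_read_set_gives_zero_depth(self):
        depth = asm.realign_reads_to_contig([], "ACGTACGT", [])
        assert depth.tolist() == [0] * 8


class TestAlignConsensus:
    def test_identity_contig_projects_full_depth_no_variants(self):
        rng = random.Random(12)
        anchor = _ins_anchor(rng)
        reads = _tiling_reads(anchor.seq)
        (cons, *_) = asm.assemble(reads, anchor, read_length_hint=60)
        ca = asm.align_consensus(cons, anchor)
        assert ca is not None
        assert ca.variants == []
        assert min(ca.depth) == 0 and max(ca.depth) == len(anchor.seq) - 1
        assert all(d > 0 for d in ca.depth.values())

    def test_sixty_bp_novel_insertion_recorded_as_one_variant(self):
        rng = random.Random(13)
        anchor = _ins_anchor(rng, flank=150, svlen=80)
        novel = "".join(rng.choice("ACGT") for _ in range(60))
        hap = anchor.seq[:40] + novel + anchor.seq[40:]
        reads = _tiling_reads(hap)
        (cons, *_) = asm.assemble(reads, anchor, read_length_hint=60)
        assert cons.contig == hap
        ca = asm.align_consensus(cons, anchor)
        ins = [v for v in ca.variants if v.kind == "I"]
        assert len(ins) == 1
        assert ins[0].length == 60
        assert ins[0].alt == novel or len(ins[0].alt) == 60

    def test_contig_without_improved_read_discarded(self):
        rng = random.Random(14)
        anchor = _ins_anchor(rng)
        reads = _tiling_reads(anchor.seq)
        for r in reads:
            r.signal.orig.score = 200.0  # original always better
        (cons, *_) = asm.assemble(reads, anchor, read_length_hint=60)
        assert asm.align_consensus(cons, anchor) is None


class TestInferAndGenotype:
    def _consensus_alignment(self, anchor, mutate=None):
        reads = _tiling_reads(anchor.seq if mutate is None else mutate)
        (cons, *_) = asm.assemble(reads, anchor, read_length_hint=60)
        ca = asm.align_consensus(cons, anchor)
        assert ca is not None
        return ca

    def test_covered_insertion_anchor_yields_call(self):
        rng = random.Random(15)
        anchor = _ins_anchor(rng, svlen=70)
        svref = SVReference([anchor], flank=150)
        ca = self._consensus_alignment(anchor)
        (call,) = asm.infer_svs([ca], anchor, svref, depth_min=3)
        assert (call.svtype, call.svlen) == ("INS", 70)
        assert call.alt_seq == anchor.sv.alt_seq

    def test_low_breakpoint_depth_blocks_call(self):
        rng = random.Random(16)
        anchor = _ins_anchor(rng, svlen=70)
        svref = SVReference([anchor], flank=150)
        ca = self._consensus_alignment(anchor)
        assert asm.infer_svs([ca], anchor, svref, depth_min=50) == []

    def test_divergent_allele_corrected_from_consensus(self):
        rng = random.Random(17)
        anchor = _ins_anchor(rng, svlen=70)
        svref = SVReference([anchor], flank=150)
        lo, _ = anchor.insert_span
        donor = list(anchor.seq)
        for off in (lo + 20, lo + 45):  # donor differs at 2 insert positions
            donor[off] = {"A": "C", "C": "G", "G": "T", "T": "A"}[donor[off]]
        ca = self._consensus_alignment(anchor, mutate="".join(donor))
        (call,) = asm.infer_svs([ca], anchor, svref, depth_min=3)
        expect = "".join(donor)[lo : lo + 70]
        assert call.alt_seq == expect
        assert call.alt_seq != anchor.sv.alt_seq

    def test_sub_50bp_calls_dropped(self):
        rng = random.Random(18)
        anchor = _ins_anchor(rng, svlen=40)
        svref = SVReference([anchor], flank=150)
        ca = self._consensus_alignment(anchor)
        assert asm.infer_svs([ca], anchor, svref, depth_min=3) == []

    @pytest.mark.parametrize(
        "alt,ref,expected",
        [(19, 1, "1/1"), (10, 10, "0/1"), (2, 18, None), (0, 0, "./.")],
    )
    def test_genotype_thresholds(self, alt, ref, expected):
        call = asm.CandidateSV("c", 100, 100, "INS", 60, "A" * 60, alt, alt, 0)
        got = asm.genotype(call, ref)
        if expected is None:
            assert got is None
        else:
            assert got.genotype == expected

    def test_left_normalize_shifts_deletion_through_homopolymer(self):
        # deleting AAAA from GGGGT AAAAA GG anywhere in the run normalizes
        # to the leftmost placement (0-based event start 5)
        ref = {"c": "GGGGTAAAAAGG"}
        call = asm.CandidateSV("c", 6, 10, "DEL", 4, "", 10, 10, 0)
        out = asm.left_normalize(call, ref)
        assert (out.pos, out.end) == (5, 9)

    def test_left_normalize_rotates_insertion(self):
        ref = {"c": "GGGGTAAAAAGG"}
        # inserting AAAA after the A-run is equivalent to inserting at its start
        call = asm.CandidateSV("c", 10, 10, "INS", 4, "AAAA", 10, 10, 0)
        out = asm.left_normalize(call, ref)
        assert out.pos == 5
        assert out.alt_seq == "AAAA"
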