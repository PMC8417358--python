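"""SV-anchor reference construction: anchors, lift-over, VCF parsing."""

import random

import pytest

from panrescue.errors import PanrescueError
from panrescue.svref import (
    SVRecord,
    build_deletion_anchor,
    build_insertion_anchor,
    build_sv_reference,
    load_sv_reference,
    parse_sv_vcf,
    write_sv_reference,
)

TOY = {"c": "AAAACCCCGGGGTTTT"}


class TestDeletionAnchor:
    def test_flanks_concatenated_around_deleted_interval(self):
        sv = SVRecord("d", "c", 8, 12, "DEL", 4)  # deletes GGGG (bases 9-12)
        a = build_deletion_anchor(TOY, sv, flank=4)
        assert a.seq == "CCCCTTTT"
        assert (a.upstream_len, a.downstream_len) == (4, 4)
        assert a.insert_span == (4, 4)

    def test_truncation_at_contig_boundaries(self):
        sv = SVRecord("d", "c", 8, 12, "DEL", 4)
        a = build_deletion_anchor(TOY, sv, flank=250)
        assert (a.upstream_len, a.downstream_len) == (8, 4)
        assert a.seq == "AAAACCCCTTTT"

    def test_default_flank_far_from_ends(self, toy_ref):
        sv = SVRecord("d", "c", 1000, 1200, "DEL", 200)
        a = build_deletion_anchor(toy_ref, sv, flank=250)
        assert len(a.seq) == 500
        # no deleted base survives in the anchor
        assert a.seq == toy_ref["c"][750:1000] + toy_ref["c"][1200:1450]

    def test_breakpoints_outside_contig_error(self):
        sv = SVRecord("d", "c", 10, 20, "DEL", 10)
        with pytest.raises(PanrescueError):
            build_deletion_anchor({"c": "ACGT" * 4}, sv)


class TestInsertionAnchor:
    def test_flank_allele_flank(self):
        sv = SVRecord("i", "c", 4, 4, "INS", 2, "GG")
        a = build_insertion_anchor({"c": "AAAATTTT"}, sv, flank=4)
        assert a.seq == "AAAAGGTTTT"
        assert a.insert_span == (4, 6)

    def test_allele_appears_exactly_once(self, toy_ref):
        allele = "TGCATGCAGGGTTACG" * 4
        sv = SVRecord("i", "c", 1500, 1500, "INS", len(allele), allele)
        a = build_insertion_anchor(toy_ref, sv, flank=250)
        assert a.seq.count(allele) == 1
        lo, hi = a.insert_span
        assert a.seq[lo:hi] == allele

    def test_dup_and_ins_code_paths_agree(self, toy_ref):
        seg = toy_ref["c"][2000:2080]
        dup = SVRecord("dup", "c", 2080, 2080, "DUP", 80, seg)
        ins = SVRecord("ins", "c", 2080, 2080, "INS", 80, seg)
        a_dup = build_insertion_anchor(toy_ref, dup, flank=100)
        a_ins = build_insertion_anchor(toy_ref, ins, flank=100)
        assert a_dup.seq == a_ins.seq
        assert a_dup.insert_span == a_ins.insert_span

    def test_empty_allele_rejected(self, toy_ref):
        with pytest.raises(PanrescueError):
            SVRecord("i", "c", 10, 10, "INS", 1, "")


class TestSVReference:
    def test_offsets_are_prefix_sums(self, toy_svref):
        lengths = [len(a.seq) for a in toy_svref.anchors]
        assert toy_svref.offsets == {0: 0, 1: lengths[0]}
        assert len(toy_svref.concat_seq) == sum(lengths)

    def test_empty_sv_list_errors(self, toy_ref):
        with pytest.raises(PanrescueError, match="no usable SV records"):
            build_sv_reference([], toy_ref)

    def test_anchor_length_law(self, toy_svref):
        for a in toy_svref.anchors:
            assert len(a.seq) == a.upstream_len + a.insert_len + a.downstream_len
            assert a.insert_len == (a.sv.svlen if a.sv.svtype != "DEL" else 0)

    def test_serialization_round_trip(self, toy_svref, tmp_path):
        write_sv_reference(toy_svref, tmp_path)
        back = load_sv_reference(tmp_path)
        assert back.concat_seq == toy_svref.concat_seq
        assert back.offsets == toy_svref.offsets
        for a, b in zip(toy_svref.anchors, back.anchors):
            assert (a.upstream_len, a.downstream_len) == (b.upstream_len, b.downstream_len)
            assert a.sv == b.sv


class TestLiftOver:
    def test_del_anchor_first_offset(self):
        sv = SVRecord("d", "c", 8, 12, "DEL", 4)
        a = build_deletion_anchor(TOY, sv, flank=4)
        lift = a.lift(0)
        assert (lift.contig, lift.position) == ("c", 5)  # the first C, 1-based
        assert not lift.shifted and not lift.inserted

    def test_del_downstream_flank_is_shifted(self):
        sv = SVRecord("d", "c", 8, 12, "DEL", 4)
        a = build_deletion_anchor(TOY, sv, flank=4)
        lift = a.lift(len(a.seq) - 1)
        assert lift.shifted
        assert lift.position == 16

    def test_insert_span_maps_to_breakpoint(self, toy_svref):
        a = toy_svref.anchors[1]  # the INS anchor
        lo, hi = a.insert_span
        for off in (lo, (lo + hi) // 2, hi - 1):
            lift = a.lift(off)
            assert lift.inserted and lift.position == a.sv.pos

    def test_round_trip_bijection_on_flanks(self, toy_svref, toy_ref):
        rng = random.Random(0)
        for a in toy_svref.anchors:
            lo, hi = a.insert_span
            flank_offsets = list(range(0, lo)) + list(range(hi, len(a.seq)))
            seen = set()
            for off in rng.sample(flank_offsets, 80):
                lift = a.lift(off)
                assert not lift.inserted
                assert lift not in seen  # injective
                seen.add(lift)
                assert a.anchor_offset_of(lift.position) == off
                # the lifted base is the very base the flank was copied from
                assert toy_ref[lift.contig][lift.position - 1] == a.seq[off]

    def test_out_of_range_offset_errors(self, toy_svref):
        with pytest.raises(PanrescueError):
            toy_svref.lift(0, len(toy_svref.anchors[0].seq))


class TestParseVCF:
    def _write(self, tmp_path, rows, contig_len=3000):
        path = tmp_path / "svs.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            f"##contig=<ID=c,length={contig_len}>\n"
            '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="t">\n'
            '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="l">\n'
            '##INFO=<ID=END,Number=1,Type=Integer,Description="e">\n'
            '##INFO=<ID=SEQ,Number=1,Type=String,Description="s">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
        )
        path.write_text(header + "".join(r + "\n" for r in rows))
        return path

    def test_explicit_del_uses_padding_convention(self, toy_ref, tmp_path):
        ref = toy_ref["c"]
        row = f"c\t8\tx\t{ref[7:12]}\t{ref[7]}\t.\tPASS\tSVTYPE=DEL"
        (sv,) = parse_sv_vcf(self._write(tmp_path, [row]), toy_ref)
        assert (sv.svtype, sv.pos, sv.end, sv.svlen) == ("DEL", 8, 12, 4)

    def test_explicit_ins(self, toy_ref, tmp_path):
        ref = toy_ref["c"]
        row = f"c\t4\tx\t{ref[3]}\t{ref[3]}GG\t.\tPASS\tSVTYPE=INS"
        (sv,) = parse_sv_vcf(self._write(tmp_path, [row]), toy_ref)
        assert (sv.svtype, sv.pos, sv.svlen, sv.alt_seq) == ("INS", 4, 2, "GG")

    def test_symbolic_del_matches_explicit_encoding(self, toy_ref, tmp_path):
        ref = toy_ref["c"]
        sym = "c\t1000\ts\tN\t<DEL>\t.\tPASS\tSVTYPE=DEL;END=1200"
        exp = f"c\t1000\te\t{ref[999:1200]}\t{ref[999]}\t.\tPASS\tSVTYPE=DEL"
        (sv_sym,) = parse_sv_vcf(self._write(tmp_path, [sym]), toy_ref)
        (sv_exp,) = parse_sv_vcf(self._write(tmp_path, [exp]), toy_ref)
        assert (sv_sym.pos, sv_sym.end, sv_sym.svlen) == (sv_exp.pos, sv_exp.end, sv_exp.svlen)
        assert sv_sym.svlen == 200

    def test_symbolic_dup_becomes_insertion_of_segment(self, toy_ref, tmp_path):
        row = "c\t2000\ts\tN\t<DUP>\t.\tPASS\tSVTYPE=DUP;END=2060"
        (sv,) = parse_sv_vcf(self._write(tmp_path, [row]), toy_ref)
        assert sv.svtype == "DUP"
        assert sv.alt_seq == toy_ref["c"][2000:2060]
        assert sv.pos == 2060  # novel junction after the duplicated copy

    def test_unsupported_and_unusable_records_skipped(self, toy_ref, tmp_path):
        rows = [
            "c\t100\tbnd\tA\tA[c:200[\t.\tPASS\t.",
            "c\t100\tinv\tN\t<INV>\t.\tPASS\tSVTYPE=INV;END=300",
            "c\t100\tins\tN\t<INS>\t.\tPASS\tSVTYPE=INS",  # no sequence
            "q\t100\tmiss\tACCA\tA\t.\tPASS\tSVTYPE=DEL",  # unknown contig
        ]
        assert parse_sv_vcf(self._write(tmp_path, rows), toy_ref) == []

    def test_duplicate_records_deduplicated_at_build(self, toy_ref, tmp_path):
        svs = [
            SVRecord("a", "c", 1000, 1200, "DEL", 200),
            SVRecord("b", "c", 1000, 1200, "DEL", 200),
        ]
        svref = build_sv_reference(svs, toy_ref, min_anchor_len=100)
        assert len(svref.anchors) == 1
        assert svref.anchors[0].sv.id == "a"
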