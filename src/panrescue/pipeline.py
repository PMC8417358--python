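"""Pipeline orchestration: build-ref, index, extract, realign, call.

All stages run single-threaded and deterministically under one seed,
which is recorded in every output header.  The stage report counts
reads and SVs at every filter so that pipeline conservation (counts
never increase downstream) can be asserted.
"""

from __future__ import annotations

import logging
import os
import random
from dataclasses import dataclass, field

import pysam
from pyfaidx import Fasta

from panrescue import assembly as asm
from panrescue.align import ScoringScheme
from panrescue.clustering import cluster_reads
from panrescue.dbg import build_index
from panrescue.errors import PanrescueError
from panrescue.pairing import Candidate, emit_sam, estimate_isize, filter_original_best
from panrescue.realign import realign_read
from panrescue.signals import extract_signal_reads, write_signal_fastq
from panrescue.svref import build_sv_reference, parse_sv_vcf, write_sv_reference
from panrescue.assembly import CandidateSV

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    flank: int = 250
    k: int = 22
    max_occ: int = 4
    top_chains: int = 12
    pair_bonus: float = 50.0
    isize_fallback: tuple[float, float] = (400.0, 50.0)
    depth_min: int | None = None  # None -> max(3, 0.2 * mean coverage)
    word_length: int = 25
    min_reads_per_contig: int = 3
    score_margin: float = 5.0
    min_svlen: int = 50
    read_length: int = 150
    seed: int = 1
    scheme: ScoringScheme = field(default_factory=ScoringScheme)

    def validate(self) -> None:
        if not 8 <= self.k <= 31:
            raise PanrescueError("k must be within [8, 31]")
        if self.flank < 1 or self.top_chains < 1 or self.max_occ < 1:
            raise PanrescueError("flank, top_chains and max_occ must be positive")
        if self.min_svlen < 1 or self.word_length < 8:
            raise PanrescueError("min_svlen/word_length out of range")


@dataclass
class PipelineResult:
    calls: list[CandidateSV]
    vcf_path: str
    sam_path: str
    report: dict


def load_reference(path: str | os.PathLike) -> dict[str, str]:
    fa = Fasta(os.fspath(path), as_raw=True)
    return {name: str(fa[name][:]).upper() for name in fa.keys()}


def gather_alignment_stats(path: str | os.PathLike, genome_length: int) -> tuple[float, list[int]]:
    """Genome-wide mean depth and an ISIZE sample from proper pairs."""
    total_bases = 0
    isizes: list[int] = []
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(os.fspath(path), mode, check_sq=False) as af:
        for read in af:
            if read.is_secondary or read.is_supplementary:
                continue
            total_bases += read.query_length or 0
            if read.is_proper_pair and read.is_read1 and read.template_length:
                isizes.append(abs(read.template_length))
                if len(isizes) >= 20000:
                    break
    return total_bases / max(1, genome_length), isizes


def _candidates_for(signal, svref, index, cfg, rng):
    if signal is None:
        return [], None
    alns = realign_read(
        signal.sequence, index, svref, cfg.scheme,
        max_occ=cfg.max_occ, top_chains=cfg.top_chains, rng=rng,
    )
    cands = [Candidate("pan", a.score, a.strand, aln=a) for a in alns]
    if signal.orig is not None:
        cands.append(Candidate("orig", signal.orig.score, signal.orig.strand,
                               orig=signal.orig))
    return cands, signal


def count_ref_support(path: str | os.PathLike, calls: list[CandidateSV],
                      margin: int = 20) -> dict[int, int]:
    """Per call, reads whose original alignment spans the breakpoint
    contiguously (full-M across [pos-margin, pos+margin])."""
    windows = [(c.contig, c.pos - margin, c.pos + margin) for c in calls]
    support = {i: 0 for i in range(len(calls))}
    if not calls:
        return support
    mode = "r" if str(path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(os.fspath(path), mode, check_sq=False) as af:
        for read in af:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            cig = read.cigartuples or []
            if not all(op in (0, 7, 8) for op, _ in cig):
                continue
            start1 = read.reference_start + 1
            end1 = start1 + sum(ln for op, ln in cig if op in (0, 2, 7, 8))
            for i, (contig, lo, hi) in enumerate(windows):
                if read.reference_name == contig and start1 <= lo and end1 >= hi:
                    support[i] += 1
    return support


def _dedupe_calls(calls: list[CandidateSV]) -> list[CandidateSV]:
    calls = sorted(calls, key=lambda c: (c.contig, c.pos, c.svtype, -c.supporting))
    out: list[CandidateSV] = []
    for c in calls:
        dup = False
        for prev in out:
            if (
                prev.contig == c.contig
                and prev.svtype == c.svtype
                and abs(prev.pos - c.pos) <= 50
                and abs(prev.svlen - c.svlen) <= max(10, 0.2 * prev.svlen)
            ):
                dup = True
                break
        if not dup:
            out.append(c)
    return out


def write_calls_vcf(
    calls: list[CandidateSV],
    reference: dict[str, str],
    path: str | os.PathLike,
    seed: int,
) -> None:
    with open(os.fspath(path), "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        out.write("##source=panrescue\n")
        out.write(f"##panrescue_seed={seed}\n")
        for name, seq in sorted(reference.items()):
            out.write(f"##contig=<ID={name},length={len(seq)}>\n")
        out.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        out.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        out.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        out.write('##INFO=<ID=RE,Number=1,Type=Integer,Description="Supporting reads">\n')
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tSAMPLE\n")
        for i, c in enumerate(sorted(calls, key=lambda c: (c.contig, c.pos))):
            seq = reference[c.contig]
            pad = seq[c.pos - 1] if c.pos >= 1 else "N"
            if c.svtype == "DEL":
                ref, alt = pad + seq[c.pos : c.end], pad
                svlen = -c.svlen
            else:
                ref, alt = pad, pad + c.alt_seq
                svlen = c.svlen
            info = f"SVTYPE={c.svtype};SVLEN={svlen};END={c.end};RE={c.supporting}"
            out.write(
                f"{c.contig}\t{c.pos}\tpanrescue_{i}\t{ref}\t{alt}\t.\tPASS\t{info}"
                f"\tGT\t{c.genotype}\n"
            )


def run_pipeline(
    ref_path: str | os.PathLike,
    known_vcf: str | os.PathLike,
    alignment_path: str | os.PathLike,
    outdir: str | os.PathLike,
    config: PipelineConfig | None = None,
) -> PipelineResult:
    """Execute all stages; intermediate files are kept under ``outdir``."""
    cfg = config or PipelineConfig()
    cfg.validate()
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    rng = random.Random(cfg.seed)
    report: dict = {"seed": cfg.seed}

    reference = load_reference(ref_path) if not isinstance(ref_path, dict) else ref_path
    genome_length = sum(len(s) for s in reference.values())

    svs = parse_sv_vcf(known_vcf, reference)
    if not svs:
        raise PanrescueError("no usable SV records")
    report["known_svs"] = len(svs)
    svref = build_sv_reference(svs, reference, flank=cfg.flank,
                               min_anchor_len=cfg.read_length)
    write_sv_reference(svref, os.path.join(outdir, "svref"))
    report["anchors"] = len(svref.anchors)

    index = build_index(svref, k=cfg.k)
    report["unitigs"] = len(index.unitigs)

    mean_depth, isize_sample = gather_alignment_stats(alignment_path, genome_length)
    model = estimate_isize(isize_sample, fallback=cfg.isize_fallback)
    report["mean_depth"] = round(mean_depth, 2)
    report["isize_mean"] = round(model.mean, 1)
    report["isize_sd"] = round(model.sd, 1)

    pairs, stats = extract_signal_reads(alignment_path, cfg.scheme)
    write_signal_fastq(pairs, os.path.join(outdir, "signals.fq"))
    report["pairs_seen"] = stats.total_pairs
    report["pairs_extracted"] = stats.emitted_pairs
    report["orphans"] = stats.orphans

    kept = []
    kept_pairs = 0
    for r1, r2 in pairs:
        c1, s1 = _candidates_for(r1, svref, index, cfg, rng)
        c2, s2 = _candidates_for(r2, svref, index, cfg, rng)
        best = filter_original_best(c1, c2, model, svref, cfg.pair_bonus)
        if best is None:
            continue
        kept_pairs += 1
        for cand, sig in ((best.c1, s1), (best.c2, s2)):
            if cand is not None and cand.source == "pan" and sig is not None:
                kept.append((sig, cand.aln, best))
    report["pairs_kept"] = kept_pairs
    report["reads_kept"] = len(kept)
    sam_path = os.path.join(outdir, "realn.sam")
    emit_sam(kept, svref, sam_path, seed=cfg.seed)

    clusters = cluster_reads(kept, svref, cfg.k, rng)
    report["clusters"] = len(clusters)

    depth_min = cfg.depth_min
    if depth_min is None:
        depth_min = max(3, int(round(0.2 * mean_depth)))
    report["depth_min"] = depth_min

    raw_calls: list[CandidateSV] = []
    n_contigs = 0
    for aid in sorted(clusters):
        cluster = clusters[aid]
        if not cluster.reads:
            continue
        reads = asm.depth_filter(cluster, mean_depth)
        if not asm.mapq_filter(reads, cfg.score_margin):
            continue
        anchor = cluster.anchor
        alignments = []
        for pool in asm.partition_blocks(reads, anchor):
            for cons in asm.assemble(pool, anchor, word=cfg.word_length,
                                     min_reads=cfg.min_reads_per_contig,
                                     read_length_hint=cfg.read_length):
                n_contigs += 1
                ca = asm.align_consensus(cons, anchor, cfg.scheme)
                if ca is not None:
                    alignments.append(ca)
        raw_calls.extend(asm.infer_svs(alignments, anchor, svref, depth_min,
                                       cfg.min_svlen))
    report["contigs"] = n_contigs
    report["raw_calls"] = len(raw_calls)

    raw_calls = _dedupe_calls(raw_calls)
    support = count_ref_support(alignment_path, raw_calls)
    calls: list[CandidateSV] = []
    for i, c in enumerate(raw_calls):
        g = asm.genotype(c, support[i])
        if g is not None:
            calls.append(asm.left_normalize(g, reference))
    report["calls"] = len(calls)

    vcf_path = os.path.join(outdir, "calls.vcf")
    write_calls_vcf(calls, reference, vcf_path, cfg.seed)
    with open(os.path.join(outdir, "report.tsv"), "w") as rep:
        for key, val in report.items():
            rep.write(f"{key}\t{val}\n")
    log.info("pipeline report: %s", report)
    return PipelineResult(calls, vcf_path, sam_path, report)
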