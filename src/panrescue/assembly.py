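"""Cluster assembly, consensus-to-anchor alignment and SV inference.

Per retained cluster the pipeline (i) drops low-score reads from 64 bp
blocks whose coverage exceeds 1.5x the genome-wide mean, (ii) discards
uncertain clusters in which over 80% of reads had original MAPQ 0 and
realignment barely improved them, (iii) assembles the surviving reads
into consensus contigs with a greedy word-overlap assembler that
records where each read joins the contig (SV regions longer than 500 bp
are assembled in 500 bp blocks), (iv) realigns reads to the contig
allowing mismatches only to obtain per-base consensus depth, (v) aligns
each contig globally to its anchor window and projects variants and
depth onto SV-reference coordinates, and (vi) calls the anchor's SV
when both breakpoints (and, for insertions, the whole inserted span)
are covered deeply enough, correcting the reported allele by the
consensus-vs-anchor variants.  Calls shorter than 50 bp are dropped;
genotypes come from the alt/(alt+ref) coverage fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from panrescue.align import DEFAULT_SCHEME, ScoringScheme, align_segment
from panrescue.clustering import ClusterRead, ReadCluster
from panrescue.svref import AnchorSequence, SVReference
from panrescue.util import revcomp

log = logging.getLogger(__name__)

DEPTH_BLOCK = 64
DEPTH_FACTOR = 1.5
MAPQ0_FRACTION = 0.8
SCORE_MARGIN = 5.0
ASSEMBLY_BLOCK = 500
WORD_LENGTH = 25
MIN_READS_PER_CONTIG = 3
MIN_EXT_SUPPORT = 2
MAX_CONTIG_MISMATCHES = 3
MIN_SVLEN = 50
HOM_FRACTION = 0.8
MIN_ALT_FRACTION = 0.2


# ---------------------------------------------------------------------------
# Read preprocessing


def depth_filter(
    cluster: ReadCluster,
    mean_depth: float,
    block: int = DEPTH_BLOCK,
    factor: float = DEPTH_FACTOR,
) -> list[ClusterRead]:
    """Trim over-covered 64 bp blocks down to ``factor`` x mean depth.

    Within each offending block the lowest-scoring reads are removed
    first (ties by read name for determinism); re-assigned reads carry
    no anchor placement and are never counted against block depth.
    """
    placed = [r for r in cluster.reads if r.aln is not None]
    floating = [r for r in cluster.reads if r.aln is None]
    if not placed:
        return list(cluster.reads)
    alen = len(cluster.anchor.seq)
    limit = factor * mean_depth
    kept = set(range(len(placed)))

    def block_depth(b0: int, b1: int) -> float:
        tot = 0
        for i in kept:
            a = placed[i].aln
            tot += max(0, min(a.anchor_end, b1) - max(a.anchor_start, b0))
        return tot / (b1 - b0)

    for b0 in range(0, alen, block):
        b1 = min(alen, b0 + block)
        while block_depth(b0, b1) > limit:
            over = [
                i for i in kept
                if placed[i].aln.anchor_start < b1 and placed[i].aln.anchor_end > b0
            ]
            if not over:
                break
            victim = min(over, key=lambda i: (placed[i].new_score, placed[i].signal.name,
                                              placed[i].signal.mate))
            kept.discard(victim)
    return [placed[i] for i in sorted(kept)] + floating


def mapq_filter(reads: list[ClusterRead], margin: float = SCORE_MARGIN) -> bool:
    """False (discard cluster) iff >80% reads had MAPQ 0 originally and
    the median realignment score gain is within ``margin``."""
    if not reads:
        return False
    mapq0 = sum(1 for r in reads if r.orig_mapq == 0)
    if mapq0 / len(reads) <= MAPQ0_FRACTION:
        return True
    gains = sorted(r.new_score - r.orig_score for r in reads)
    median = gains[len(gains) // 2] if len(gains) % 2 else 0.5 * (
        gains[len(gains) // 2 - 1] + gains[len(gains) // 2]
    )
    return median > margin


# ---------------------------------------------------------------------------
# Greedy word-overlap assembly


@dataclass
class Consensus:
    contig: str
    members: list[tuple[int, int]]  # (read index into pool, join position on contig)
    depth: np.ndarray | None = None
    block_index: int = 0
    reads: list[ClusterRead] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.contig)


def _oriented(read: ClusterRead) -> str:
    if read.aln is not None and read.aln.strand == "-":
        return revcomp(read.signal.sequence)
    return read.signal.sequence


def assemble(
    reads: list[ClusterRead],
    anchor: AnchorSequence,
    word: int = WORD_LENGTH,
    min_reads: int = MIN_READS_PER_CONTIG,
    min_support: int = MIN_EXT_SUPPORT,
    read_length_hint: int | None = None,
) -> list[Consensus]:
    """Greedy majority assembly of a cluster (one 500 bp block's reads).

    The most frequent unused word seeds the contig, which is extended
    base by base in both directions by the majority vote of reads whose
    word overlap reaches the contig end; each read's join position is
    recorded the moment it first supports the contig.
    """
    pool = [_oriented(r) for r in reads]
    min_len = read_length_hint or (max((len(s) for s in pool), default=0))
    used = [False] * len(pool)
    out: list[Consensus] = []

    def words_of(seq: str):
        for i in range(len(seq) - word + 1):
            yield i, seq[i : i + word]

    while True:
        unused = [i for i in range(len(pool)) if not used[i] and len(pool[i]) >= word]
        if len(unused) < min_reads:
            break
        freq: dict[str, set[int]] = {}
        for i in unused:
            for _off, w in words_of(pool[i]):
                freq.setdefault(w, set()).add(i)
        best_word, support = max(freq.items(), key=lambda kv: (len(kv[1]), kv[0]))
        if len(support) < min_reads:
            break
        contig = best_word

        def extend(contig: str, rightwards: bool) -> str:
            while True:
                probe = contig[-word:] if rightwards else contig[:word]
                votes: dict[str, int] = {}
                for i in unused:
                    seq = pool[i]
                    start = 0
                    while True:
                        j = seq.find(probe, start)
                        if j < 0:
                            break
                        if rightwards and j + word < len(seq):
                            b = seq[j + word]
                            votes[b] = votes.get(b, 0) + 1
                        elif not rightwards and j > 0:
                            b = seq[j - 1]
                            votes[b] = votes.get(b, 0) + 1
                        start = j + 1
                if not votes:
                    return contig
                base, cnt = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
                # majority rule where coverage exists; a lone voter may extend
                # the contig edge only when it is unanimous
                if cnt < min_support and cnt != sum(votes.values()):
                    return contig
                contig = contig + base if rightwards else base + contig
                if len(contig) > 20000:  # safety against repeat cycling
                    return contig
            return contig

        contig = extend(contig, rightwards=True)
        contig = extend(contig, rightwards=False)

        # Membership + join positions: first exact word shared with the
        # contig.  Every pool read joins for depth purposes (reads spanning
        # the seam between two contigs support both), but only previously
        # unused reads count as the contig's own members and are consumed.
        contig_words = {w: off for off, w in list(words_of(contig))[::-1]}
        members: list[tuple[int, int]] = []
        member_reads: list[ClusterRead] = []
        fresh = 0
        for i in range(len(pool)):
            if len(pool[i]) < word:
                continue
            join = None
            for off, w in words_of(pool[i]):
                hit = contig_words.get(w)
                if hit is not None:
                    join = hit - off
                    break
            if join is not None:
                members.append((i, join))
                member_reads.append(reads[i])
                if not used[i]:
                    fresh += 1
                    used[i] = True
        if len(contig) >= min_len and len(members) >= min_reads:
            cons = Consensus(contig, members, reads=member_reads)
            cons.depth = realign_reads_to_contig(
                [pool[i] for i, _ in members], contig, [j for _, j in members]
            )
            out.append(cons)
        if fresh == 0:  # defensive: avoid livelock
            for i in support:
                used[i] = True
    return out


def realign_reads_to_contig(
    sequences: list[str],
    contig: str,
    joins: list[int],
    max_mm: int = MAX_CONTIG_MISMATCHES,
) -> np.ndarray:
    """Mismatch-only placement of reads at their join positions -> depth vector."""
    depth = np.zeros(len(contig), dtype=np.int32)
    for seq, join in zip(sequences, joins):
        c0 = max(0, join)
        c1 = min(len(contig), join + len(seq))
        if c1 <= c0:
            continue
        r0 = c0 - join
        seg = seq[r0 : r0 + (c1 - c0)]
        mism = sum(1 for a, b in zip(seg, contig[c0:c1]) if a != b)
        if mism > max_mm:
            continue
        depth[c0:c1] += 1
    return depth


def partition_blocks(reads: list[ClusterRead], anchor: AnchorSequence,
                     block: int = ASSEMBLY_BLOCK) -> list[list[ClusterRead]]:
    """Partition a long SV region into 500 bp assembly blocks by read start.

    Reads without an anchor placement (re-assigned) join every block's
    pool only through block 0 to avoid double counting.
    """
    if anchor.sv.svlen <= block:
        return [list(reads)]
    n_blocks = (len(anchor.seq) + block - 1) // block
    pools: list[list[ClusterRead]] = [[] for _ in range(n_blocks)]
    for r in reads:
        if r.aln is None:
            pools[0].append(r)
        else:
            pools[min(n_blocks - 1, r.aln.anchor_start // block)].append(r)
    return [p for p in pools if p]


# ---------------------------------------------------------------------------
# Consensus-to-anchor alignment


@dataclass
class Variant:
    kind: str  # "X" mismatch, "I" insertion, "D" deletion
    anchor_pos: int  # 0-based anchor coordinate (position of/after the event)
    length: int
    alt: str = ""  # substituted/inserted consensus bases


@dataclass
class ConsensusAlignment:
    anchor_id: int
    anchor_start: int
    variants: list[Variant]
    depth: dict[int, int]  # anchor position -> consensus read depth
    score: float
    consensus: Consensus


def align_consensus(
    cons: Consensus,
    anchor: AnchorSequence,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    window_pad: int = 50,
) -> ConsensusAlignment | None:
    """NW alignment of a contig against candidate anchor windows.

    Candidate positions are the supporting reads' anchor placements
    projected to contig origin, de-duplicated within 50 bp.  A contig
    with all candidates out of range, or none of whose reads improved
    on its original alignment score, is discarded.
    """
    cands: list[int] = []
    improved = False
    for r in cons.reads:
        if r.new_score > r.orig_score:
            improved = True
    for (r, join) in zip(cons.reads, (j for _i, j in cons.members)):
        if r.aln is None:
            continue
        cands.append(r.aln.anchor_start - join)
    if not improved:
        log.debug("consensus dropped: no read improved on its original score")
        return None
    cands = sorted(set(cands))
    dedup: list[int] = []
    for c in cands:
        if not dedup or c - dedup[-1] > 50:
            dedup.append(c)
    dedup = [c for c in dedup if -len(cons.contig) < c < len(anchor.seq)]
    if not dedup:
        log.debug("consensus dropped: all candidate positions out of range")
        return None

    best: ConsensusAlignment | None = None
    for cand in dedup:
        w0 = max(0, cand - window_pad)
        w1 = min(len(anchor.seq), cand + len(cons.contig) + window_pad)
        window = anchor.seq[w0:w1]
        # free query ends: contigs may legitimately overhang the anchor
        # (reads reach into the genome beyond the flanks); the overhang is
        # clipped rather than forced into the window
        seg = align_segment(window, cons.contig, scheme, free_t_left=True,
                            free_t_right=True, free_q_left=True, free_q_right=True)
        if not seg.ops:
            continue
        variants: list[Variant] = []
        depth: dict[int, int] = {}
        t = seg.t_start
        q = seg.q_start
        for op, ln in seg.ops:
            if op == "M":
                for i in range(ln):
                    apos = w0 + t + i
                    depth[apos] = depth.get(apos, 0) + int(cons.depth[q + i])
                    if window[t + i] != cons.contig[q + i]:
                        variants.append(Variant("X", apos, 1, cons.contig[q + i]))
                t += ln
                q += ln
            elif op == "D":  # anchor bases absent from consensus -> deletion
                variants.append(Variant("D", w0 + t, ln))
                t += ln
            elif op == "I":  # consensus bases absent from anchor -> insertion
                variants.append(Variant("I", w0 + t, ln, cons.contig[q : q + ln]))
                q += ln
        ca = ConsensusAlignment(anchor.anchor_id, w0 + seg.t_start, variants, depth,
                                seg.score, cons)
        if best is None or ca.score > best.score:
            best = ca
    return best


# ---------------------------------------------------------------------------
# SV inference and genotyping


@dataclass
class CandidateSV:
    contig: str
    pos: int  # 1-based padding-base position (VCF convention)
    end: int
    svtype: str
    svlen: int
    alt_seq: str
    alt_depth: int
    supporting: int
    anchor_id: int
    genotype: str = "./."


def _aggregate_depth(alignments: list[ConsensusAlignment]) -> dict[int, int]:
    """Per-position max across contigs: overlapping contigs share reads, so
    summing would double-count; the deepest contig carries the local truth."""
    depth: dict[int, int] = {}
    for ca in alignments:
        for pos, d in ca.depth.items():
            if d > depth.get(pos, 0):
                depth[pos] = d
    return depth


JUNCTION_WINDOW = 50  # tolerated breakpoint jitter between panel and donor


def _apply_variants(segment: list[str], variants: list[Variant], offset: int) -> None:
    """Apply X/I/D variants (anchor coordinates, right-to-left) in place."""
    for v in sorted(variants, key=lambda v: -v.anchor_pos):
        i = v.anchor_pos - offset
        if i < 0 or i > len(segment):
            continue
        if v.kind == "X":
            if i < len(segment):
                segment[i] = v.alt
        elif v.kind == "D":
            del segment[i : i + v.length]
        elif v.kind == "I":
            segment[i:i] = list(v.alt)


def infer_svs(
    alignments: list[ConsensusAlignment],
    anchor: AnchorSequence,
    svref: SVReference,
    depth_min: int,
    min_svlen: int = MIN_SVLEN,
) -> list[CandidateSV]:
    """Call the anchor's own SV (and large novel indels seen in consensus).

    Known-panel breakpoints may be jittered relative to the donor, so
    junction depth is evaluated over a +/-50 bp window around each
    breakpoint, and the reported allele/length is corrected by *all*
    consensus-vs-anchor variants inside the widened insert window:
    applying them to the anchor window reconstructs the donor's local
    haplotype, whose inner segment is the (rotation-consistent) donor
    allele at the panel position.  Additional >= ``min_svlen`` indels
    seen outside the window become extra calls at their lifted genome
    positions; calls shorter than ``min_svlen`` are dropped.
    """
    if not alignments:
        return []
    depth = _aggregate_depth(alignments)
    # overlapping contigs report the same event twice; keep one copy
    variants = sorted(
        {(v.kind, v.anchor_pos, v.length, v.alt) for ca in alignments for v in ca.variants}
    )
    variants = [Variant(k, p, ln, alt) for k, p, ln, alt in variants]
    supporting = len({
        (r.signal.name, r.signal.mate) for ca in alignments for r in ca.consensus.reads
    })
    sv = anchor.sv
    lo, hi = anchor.insert_span
    alen = len(anchor.seq)
    out: list[CandidateSV] = []

    def d(pos: int) -> int:
        return depth.get(pos, 0)

    w0 = max(0, lo - JUNCTION_WINDOW)
    w1 = min(alen, hi + JUNCTION_WINDOW)
    in_window = [v for v in variants if w0 <= v.anchor_pos < w1]
    deleted = set()
    for v in in_window:
        if v.kind == "D":
            deleted.update(range(v.anchor_pos, v.anchor_pos + v.length))

    left_depth = max((d(p) for p in range(w0, lo)), default=d(max(0, lo - 1)))
    right_depth = max((d(p) for p in range(hi, w1)), default=d(min(alen - 1, hi)))
    ok = left_depth >= depth_min and right_depth >= depth_min
    if sv.svtype in ("INS", "DUP") and ok:
        # Interior coverage confirms the assembled allele end to end.  The
        # junction test above carries the call's evidence at depth_min; the
        # interior is judged per 64 bp block mean at half that threshold,
        # because per-base minima over a kilobase of heterozygous insert
        # (alt coverage ~ mean/3 after extraction) would reject calls on
        # single-base sampling dips while an uncovered insert still scores 0.
        interior_min = max(3, depth_min // 2)
        ok = hi > lo
        for b0 in range(lo, hi, DEPTH_BLOCK):
            b1 = min(hi, b0 + DEPTH_BLOCK)
            covered = [p for p in range(b0, b1) if p not in deleted]
            if not covered:
                continue
            if sum(d(p) for p in covered) / len(covered) < interior_min:
                ok = False
                break
    if ok:
        net = sum(v.length for v in in_window if v.kind == "I") - sum(
            v.length for v in in_window if v.kind == "D"
        )
        if sv.svtype == "DEL":
            allele = ""
            svlen = sv.svlen - net  # extra consensus deletion = longer DEL
            end = sv.pos + svlen
        else:
            window = list(anchor.seq[w0:w1])
            _apply_variants(window, in_window, w0)
            w_left, w_right = lo - w0, w1 - hi
            svlen = len(window) - w_left - w_right
            allele = "".join(window[w_left : w_left + max(0, svlen)])
            end = sv.pos
        if svlen >= min_svlen:
            out.append(
                CandidateSV(
                    contig=sv.contig,
                    pos=sv.pos,
                    end=end,
                    svtype=sv.svtype,
                    svlen=svlen,
                    alt_seq=allele,
                    alt_depth=min(left_depth, right_depth),
                    supporting=supporting,
                    anchor_id=anchor.anchor_id,
                )
            )

    # Large novel indels away from the known junction.
    for v in variants:
        if v.kind == "X" or v.length < min_svlen:
            continue
        if w0 <= v.anchor_pos < w1:
            continue  # already folded into the corrected call
        lift = anchor.lift(min(v.anchor_pos, alen - 1))
        if lift.inserted:
            continue
        pos1 = lift.position - 1  # padding base before the event
        if v.kind == "D":
            out.append(CandidateSV(sv.contig, pos1, pos1 + v.length, "DEL", v.length,
                                   "", d(max(0, v.anchor_pos - 1)), supporting,
                                   anchor.anchor_id))
        else:
            out.append(CandidateSV(sv.contig, pos1, pos1, "INS", v.length, v.alt,
                                   d(max(0, v.anchor_pos - 1)), supporting,
                                   anchor.anchor_id))
    return out


def genotype(call: CandidateSV, ref_depth: int) -> CandidateSV | None:
    """Coverage genotyping: alt fraction >= 0.8 hom, >= 0.2 het, else noise.

    Returns the call with its genotype set, or None when the alt
    fraction is below the noise floor.  Zero total depth yields './.'.
    """
    total = call.alt_depth + max(0, ref_depth)
    if total == 0:
        call.genotype = "./."
        return call
    frac = call.alt_depth / total
    if frac >= HOM_FRACTION:
        call.genotype = "1/1"
    elif frac >= MIN_ALT_FRACTION:
        call.genotype = "0/1"
    else:
        return None
    return call


def left_normalize(call: CandidateSV, reference) -> CandidateSV:
    """Shift an indel call to its leftmost equivalent position."""
    seq = str(reference[call.contig]).upper()
    pos = call.pos  # 1-based padding base == 0-based event start
    if call.svtype == "DEL":
        allele = list(seq[pos : call.end])
        while pos > 0 and allele and seq[pos - 1] == allele[-1]:
            allele = [seq[pos - 1]] + allele[:-1]
            pos -= 1
        call.pos = pos
        call.end = pos + call.svlen
    else:
        allele = list(call.alt_seq)
        while pos > 0 and allele and seq[pos - 1] == allele[-1]:
            allele = [seq[pos - 1]] + allele[:-1]
            pos -= 1
        call.pos = pos
        call.end = pos
        call.alt_seq = "".join(allele)
    return call
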