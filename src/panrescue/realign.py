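"""Single-end realignment of signal reads against the SV reference.

Seeding selects unique k-mers (occurrence count bounded by ``max_occ``
in the SV reference), always admitting the first and last k-mer of the
read so that reads lying entirely in repeat tracts still seed at their
ends.  Seeds are first merged within index unitigs into long match
blocks, blocks are expanded to reference positions (randomly capped at
1000 positions for hyper-repetitive blocks), chained with sparse DP,
and the top chains are extended: exact blocks are kept verbatim, the
gaps between blocks are closed with global alignment, and the read ends
beyond the outer blocks are extended semi-globally with soft clipping
where extension does not pay.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import NamedTuple

from panrescue.align import DEFAULT_SCHEME, ScoringScheme, align_segment, ops_to_cigar
from panrescue.chain import ChainSeed, SeedChain, sdp_chain
from panrescue.dbg import DBGIndex
from panrescue.svref import SVReference
from panrescue.util import revcomp

DEFAULT_MAX_OCC = 4
DEFAULT_TOP_CHAINS = 12
MAX_BLOCK_POSITIONS = 1000
_END_PAD = 30  # extra anchor bases offered to end extension


class UnitigSeed(NamedTuple):
    """A k-mer seed located in unitig coordinates (position expansion deferred)."""

    read_off: int
    unitig_id: int
    unitig_off: int


@dataclass
class SingleEndAlignment:
    anchor_id: int
    anchor_start: int
    anchor_end: int
    read_start: int
    read_end: int
    strand: str
    cigar: str
    score: float
    mismatches: int
    source: str = "pan"  # "pan" (realigned) or "orig" (original aligner)


def select_seeds(read: str, index: DBGIndex, max_occ: int = DEFAULT_MAX_OCC) -> list[UnitigSeed]:
    """Unique-k-mer seeds for one oriented read, plus both end k-mers."""
    k = index.k
    n = len(read)
    if n < k:
        return []
    out = []
    last = n - k
    for i in range(last + 1):
        km = read[i : i + k]
        if "N" in km:
            continue
        hit = index.kmer_map.get(km)
        if hit is None:
            continue
        uid, off = hit
        if i == 0 or i == last or index.occ_count(uid, off) <= max_occ:
            out.append(UnitigSeed(i, uid, off))
    return out


def merge_in_unitig(
    seeds: list[UnitigSeed],
    index: DBGIndex,
    strand: str = "+",
    rng: random.Random | None = None,
    max_positions: int = MAX_BLOCK_POSITIONS,
) -> list[ChainSeed]:
    """Merge co-linear in-unitig seeds into blocks and expand to positions.

    Seeds on the same unitig diagonal whose read offsets are within one
    k of each other merge into a single exact-match block (the union
    span).  Each block is then mapped to SV-reference positions through
    the unitig occurrence list; blocks with more than ``max_positions``
    placements keep a random subset of exactly that size.
    """
    if not seeds:
        return []
    k = index.k
    rng = rng or random.Random(0)
    seeds = sorted(seeds, key=lambda s: (s.unitig_id, s.unitig_off - s.read_off, s.read_off))
    blocks: list[tuple[int, int, int, int]] = []  # (read_off, uid, uoff, length)
    cur = None
    for s in seeds:
        if (
            cur is not None
            and s.unitig_id == cur[1]
            and (s.unitig_off - s.read_off) == (cur[2] - cur[0])
            and 0 <= s.read_off - (cur[0] + cur[3] - k) <= k
        ):
            cur = (cur[0], cur[1], cur[2], s.read_off + k - cur[0])
        else:
            if cur is not None:
                blocks.append(cur)
            cur = (s.read_off, s.unitig_id, s.unitig_off, k)
    if cur is not None:
        blocks.append(cur)

    out: list[ChainSeed] = []
    svref = index.svref
    for read_off, uid, uoff, length in blocks:
        n_span = length - k + 1
        positions = index.span_positions(uid, uoff, n_span)
        if len(positions) > max_positions:
            positions = sorted(rng.sample(positions, max_positions))
        for pos in positions:
            aid, aoff = svref.anchor_at(pos)
            out.append(ChainSeed(read_off, length, aid, aoff, strand))
    return out


def extend(
    read: str,
    chain: SeedChain,
    svref: SVReference,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> SingleEndAlignment | None:
    """Extend one seed chain to a full alignment of the oriented read.

    ``read`` must already be oriented to the chain's strand (reverse
    complemented by the caller for '-' chains).
    """
    anchor = svref.anchor(chain.anchor_id)
    aseq = anchor.seq
    seeds = _trim_overlaps(chain.seeds)
    if not seeds:
        return None
    ops: list[tuple[str, int]] = []
    score = 0.0
    mism = 0

    first = seeds[0]
    qseg = read[: first.read_off]
    clip_left = 0
    astart = first.anchor_off
    if qseg:
        t0 = max(0, first.anchor_off - len(qseg) - _END_PAD)
        seg = align_segment(aseq[t0 : first.anchor_off], qseg, scheme,
                            free_t_left=True, free_q_left=True)
        clip_left = seg.q_start
        astart = t0 + seg.t_start if seg.ops else first.anchor_off
        if not seg.ops:
            clip_left = len(qseg)
        ops.extend(seg.ops)
        score += seg.score
        mism += seg.mismatches

    prev = None
    for s in seeds:
        if prev is not None:
            qgap = read[prev.read_end : s.read_off]
            tgap = aseq[prev.anchor_end : s.anchor_off]
            seg = align_segment(tgap, qgap, scheme)
            ops.extend(seg.ops)
            score += seg.score
            mism += seg.mismatches
        ops.append(("M", s.length))
        score += s.length * scheme.match
        prev = s

    last = seeds[-1]
    qseg = read[last.read_end :]
    aend = last.anchor_end
    clip_right = 0
    if qseg:
        t1 = min(len(aseq), last.anchor_end + len(qseg) + _END_PAD)
        seg = align_segment(aseq[last.anchor_end : t1], qseg, scheme,
                            free_t_right=True, free_q_right=True)
        if seg.ops:
            aend = last.anchor_end + seg.t_end
            clip_right = len(qseg) - seg.q_end
        else:
            clip_right = len(qseg)
        ops.extend(seg.ops)
        score += seg.score
        mism += seg.mismatches

    full_ops = []
    if clip_left:
        full_ops.append(("S", clip_left))
    full_ops.extend(ops)
    if clip_right:
        full_ops.append(("S", clip_right))
    merged = []
    for op, ln in full_ops:
        if ln <= 0:
            continue
        if merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + ln)
        else:
            merged.append((op, ln))
    return SingleEndAlignment(
        anchor_id=chain.anchor_id,
        anchor_start=astart,
        anchor_end=aend,
        read_start=clip_left,
        read_end=len(read) - clip_right,
        strand=chain.strand,
        cigar=ops_to_cigar(merged),
        score=score,
        mismatches=mism,
    )


def _trim_overlaps(seeds: list[ChainSeed]) -> list[ChainSeed]:
    """Trim block starts so consecutive blocks never overlap in read or anchor."""
    out: list[ChainSeed] = []
    for s in sorted(seeds, key=lambda b: b.read_off):
        if out:
            p = out[-1]
            t = max(0, p.read_end - s.read_off, p.anchor_end - s.anchor_off)
            if t >= s.length:
                continue
            if t:
                s = ChainSeed(s.read_off + t, s.length - t, s.anchor_id, s.anchor_off + t, s.strand)
        out.append(s)
    return out


def realign_read(
    seq: str,
    index: DBGIndex,
    svref: SVReference,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    max_occ: int = DEFAULT_MAX_OCC,
    top_chains: int = DEFAULT_TOP_CHAINS,
    rng: random.Random | None = None,
) -> list[SingleEndAlignment]:
    """Full single-end realignment: seed, chain, extend; results by score."""
    rng = rng or random.Random(0)
    blocks: list[ChainSeed] = []
    oriented = {"+": seq.upper(), "-": revcomp(seq.upper())}
    for strand, s in oriented.items():
        seeds = select_seeds(s, index, max_occ)
        blocks.extend(merge_in_unitig(seeds, index, strand=strand, rng=rng))
    chains = sdp_chain(blocks)
    results: list[SingleEndAlignment] = []
    seen: set[tuple[int, int, str]] = set()
    for chain in chains[:top_chains]:
        aln = extend(oriented[chain.strand], chain, svref, scheme)
        if aln is None:
            continue
        key = (aln.anchor_id, aln.anchor_start, aln.strand)
        if key in seen:
            continue
        seen.add(key)
        results.append(aln)
    results.sort(key=lambda a: (-a.score, a.anchor_id, a.anchor_start))
    return results
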