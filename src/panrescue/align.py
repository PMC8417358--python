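"""Pairwise alignment primitives shared by extension and consensus steps.

Dynamic programming is delegated to Bio.Align.PairwiseAligner; this
module fixes the scoring scheme, converts aligner output into CIGAR-like
operation lists, and exposes the three flavours the pipeline needs:
fully global (gap filling between chained blocks and consensus-to-anchor
alignment) and left/right semi-global end extension where unaligned read
prefixes/suffixes become soft clips.

The default scheme is BWA-MEM-like: match +1, mismatch -4, gap open -6
for the first gapped base and -1 per additional base, so a length-L gap
scores -(6 + L - 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

from Bio import Align


@dataclass(frozen=True)
class ScoringScheme:
    match: int = 1
    mismatch: int = -4
    gap_open: int = -6
    gap_extend: int = -1

    def gap_score(self, length: int) -> int:
        if length <= 0:
            return 0
        return self.gap_open + (length - 1) * self.gap_extend

    def read_score(self, aligned_len: int, mismatches: int, gap_lengths=()) -> int:
        """Comparable score for an alignment described only by its stats."""
        s = (aligned_len - mismatches) * self.match + mismatches * self.mismatch
        for g in gap_lengths:
            s += self.gap_score(g)
        return s


DEFAULT_SCHEME = ScoringScheme()


def _aligner(scheme: ScoringScheme) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scheme.match
    a.mismatch_score = scheme.mismatch
    a.open_gap_score = scheme.gap_open
    a.extend_gap_score = scheme.gap_extend
    return a


class SegAlignment(NamedTuple):
    """Alignment of query[q_start:q_end] against target[t_start:t_end]."""

    ops: list  # [(op, length)] with op in 'M', 'I' (query extra), 'D' (target extra)
    score: float
    t_start: int
    t_end: int
    q_start: int
    q_end: int
    mismatches: int


def align_segment(
    target: str,
    query: str,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    free_t_left: bool = False,
    free_q_left: bool = False,
    free_t_right: bool = False,
    free_q_right: bool = False,
) -> SegAlignment:
    """Align query to target; free end gaps make the alignment semi-global.

    With no free ends this is plain Needleman-Wunsch.  Free query ends
    leave the corresponding part of the query unaligned (soft clip);
    free target ends let the query land inside the target window.
    """
    if not query and not target:
        return SegAlignment([], 0.0, 0, 0, 0, 0, 0)
    if not query:
        if free_t_left or free_t_right:
            return SegAlignment([], 0.0, 0, 0, 0, 0, 0)
        return SegAlignment([("D", len(target))], scheme.gap_score(len(target)), 0, len(target), 0, 0, 0)
    if not target:
        if free_q_left or free_q_right:
            return SegAlignment([], 0.0, 0, 0, 0, 0, 0)
        return SegAlignment([("I", len(query))], scheme.gap_score(len(query)), 0, 0, 0, len(query), 0)

    a = _aligner(scheme)
    # Biopython >= 1.88 naming: target gaps are "insertions", query gaps
    # are "deletions" (relative to the target).
    if free_t_left:
        a.open_left_insertion_score = 0
        a.extend_left_insertion_score = 0
    if free_t_right:
        a.open_right_insertion_score = 0
        a.extend_right_insertion_score = 0
    if free_q_left:
        a.open_left_deletion_score = 0
        a.extend_left_deletion_score = 0
    if free_q_right:
        a.open_right_deletion_score = 0
        a.extend_right_deletion_score = 0
    al = a.align(target, query)[0]
    tblocks, qblocks = al.aligned
    if len(tblocks) == 0:
        return SegAlignment([], 0.0, 0, 0, 0, 0, 0)

    ops: list[tuple[str, int]] = []
    mism = 0
    t_start = int(tblocks[0][0])
    q_start = int(qblocks[0][0])
    # End gaps outside [t_start, t_end) x [q_start, q_end) are either free
    # (semi-global) or must be charged as real indels (global).
    prev_t, prev_q = t_start, q_start
    for (tb0, tb1), (qb0, qb1) in zip(tblocks, qblocks):
        tb0, tb1, qb0, qb1 = int(tb0), int(tb1), int(qb0), int(qb1)
        if tb0 > prev_t:
            ops.append(("D", tb0 - prev_t))
        if qb0 > prev_q:
            ops.append(("I", qb0 - prev_q))
        ops.append(("M", tb1 - tb0))
        mism += sum(1 for x, y in zip(target[tb0:tb1], query[qb0:qb1]) if x != y)
        prev_t, prev_q = tb1, qb1
    t_end, q_end = prev_t, prev_q

    # Charge non-free end gaps so SegAlignment is self-consistent.
    if q_start > 0 and not (free_q_left or free_t_left):
        ops.insert(0, ("I", q_start))
        q_start = 0
    if t_start > 0 and not (free_t_left or free_q_left):
        ops.insert(0, ("D", t_start))
        t_start = 0
    if q_end < len(query) and not (free_q_right or free_t_right):
        ops.append(("I", len(query) - q_end))
        q_end = len(query)
    if t_end < len(target) and not (free_t_right or free_q_right):
        ops.append(("D", len(target) - t_end))
        t_end = len(target)
    return SegAlignment(_merge_ops(ops), float(al.score), t_start, t_end, q_start, q_end, mism)


def _merge_ops(ops):
    out = []
    for op, ln in ops:
        if ln <= 0:
            continue
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + ln)
        else:
            out.append((op, ln))
    return out


def ops_to_cigar(ops) -> str:
    return "".join(f"{ln}{op}" for op, ln in ops) or "*"


def cigar_to_ops(cigar: str):
    ops = []
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            ops.append((ch, int(num)))
            num = ""
    return ops
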