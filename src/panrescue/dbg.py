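"""De Bruijn graph k-mer index over the SV reference.

The index mirrors the unitig-centric design of read-alignment dBG
indexes: the k-mers of all anchors form a de Bruijn graph whose maximal
non-branching paths (unitigs) are materialized once; every k-mer maps to
a unique (unitig, offset), and each unitig keeps the list of positions
where it occurs in the concatenated SV reference.  A k-mer occurrence is
then a unitig occurrence plus the k-mer's offset, which is what lets
consecutive seeds be merged into long match blocks *within* a unitig
before any position expansion happens.

Unitig occurrence runs are recorded with their covered offset interval,
so lookups stay exact even when a unitig is clipped at an anchor
boundary or at an ambiguous base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, NamedTuple

from panrescue.errors import PanrescueError
from panrescue.svref import SVReference

DEFAULT_K = 22


class UnitigRun(NamedTuple):
    """One occurrence of (part of) a unitig in the concatenated reference.

    ``pos`` is the concat-coordinate of the k-mer at offset ``off_lo``;
    the run covers unitig k-mer offsets ``[off_lo, off_hi)``.
    """

    pos: int
    off_lo: int
    off_hi: int


class Occurrence(NamedTuple):
    unitig_id: int
    offset: int
    count: int
    positions: tuple[int, ...]  # concat-seq coordinates, sorted


@dataclass
class DBGIndex:
    k: int
    unitigs: list[str]
    kmer_map: dict[str, tuple[int, int]]
    runs: list[list[UnitigRun]] = field(repr=False)  # per unitig_id, sorted by pos
    svref: SVReference = field(repr=False, default=None)

    def n_kmers(self, unitig_id: int) -> int:
        return len(self.unitigs[unitig_id]) - self.k + 1

    def occ_count(self, unitig_id: int, offset: int) -> int:
        return sum(1 for r in self.runs[unitig_id] if r.off_lo <= offset < r.off_hi)

    def span_positions(self, unitig_id: int, off_lo: int, n: int) -> list[int]:
        """Concat positions where k-mer offsets [off_lo, off_lo+n) all occur."""
        out = []
        for r in self.runs[unitig_id]:
            if r.off_lo <= off_lo and off_lo + n <= r.off_hi:
                out.append(r.pos + (off_lo - r.off_lo))
        return sorted(out)

    def lookup(self, kmer: str) -> Occurrence | None:
        if len(kmer) != self.k:
            raise PanrescueError(f"lookup requires a {self.k}-mer")
        if "N" in kmer:
            return None
        hit = self.kmer_map.get(kmer)
        if hit is None:
            return None
        uid, off = hit
        pos = tuple(self.span_positions(uid, off, 1))
        return Occurrence(uid, off, len(pos), pos)


def lookup(index: DBGIndex, kmer: str) -> Occurrence | None:
    return index.lookup(kmer)


def _segments(seq: str, k: int) -> Iterator[tuple[int, str]]:
    """Maximal N-free segments of length >= k as (start, subseq)."""
    start = 0
    for i, base in enumerate(seq):
        if base == "N":
            if i - start >= k:
                yield start, seq[start:i]
            start = i + 1
    if len(seq) - start >= k:
        yield start, seq[start:]


def build_index(svref: SVReference, k: int = DEFAULT_K) -> DBGIndex:
    if not 8 <= k <= 31:
        raise PanrescueError("k must be within [8, 31]")
    # Edge multiplicity per (k-1)-mer node, from every N-free segment.
    kmer_set: set[str] = set()
    in_b: dict[str, set[str]] = {}
    out_b: dict[str, set[str]] = {}
    anchor_segments: list[tuple[int, int, str]] = []  # (concat_start, anchor_id, segment)
    for a in svref.anchors:
        if len(a.seq) < k:
            continue
        base_off = svref.offsets[a.anchor_id]
        for seg_start, seg in _segments(a.seq.upper(), k):
            anchor_segments.append((base_off + seg_start, a.anchor_id, seg))
            for i in range(len(seg) - k + 1):
                km = seg[i : i + k]
                if km in kmer_set:
                    continue
                kmer_set.add(km)
                out_b.setdefault(km[:-1], set()).add(km[-1])
                in_b.setdefault(km[1:], set()).add(km[0])

    def succ(km: str) -> str | None:
        m = km[1:]
        if len(out_b.get(m, ())) == 1 and len(in_b.get(m, ())) == 1:
            return m + next(iter(out_b[m]))
        return None

    def pred(km: str) -> str | None:
        m = km[:-1]
        if len(in_b.get(m, ())) == 1 and len(out_b.get(m, ())) == 1:
            return next(iter(in_b[m])) + m
        return None

    unitigs: list[str] = []
    kmer_map: dict[str, tuple[int, int]] = {}
    visited: set[str] = set()

    def walk(start: str) -> None:
        uid = len(unitigs)
        chain = [start]
        visited.add(start)
        cur = start
        while True:
            nxt = succ(cur)
            if nxt is None or nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        unitigs.append(chain[0] + "".join(km[-1] for km in chain[1:]))
        for off, km in enumerate(chain):
            kmer_map[km] = (uid, off)

    for km in sorted(kmer_set):
        if km not in visited and pred(km) is None:
            walk(km)
    for km in sorted(kmer_set):  # cycles (pure tandem repeats)
        if km not in visited:
            walk(km)

    # Occurrence runs: scan each segment, grouping consecutive positions
    # that advance through the same unitig.
    runs: list[list[UnitigRun]] = [[] for _ in unitigs]
    for seg_concat_start, _aid, seg in anchor_segments:
        run_uid = run_lo = run_start = None
        prev = None  # (uid, off)
        for i in range(len(seg) - k + 1):
            uid, off = kmer_map[seg[i : i + k]]
            if prev is not None and prev == (uid, off - 1):
                prev = (uid, off)
                continue
            if prev is not None:
                runs[run_uid].append(UnitigRun(run_start, run_lo, prev[1] + 1))
            run_uid, run_lo = uid, off
            run_start = seg_concat_start + i
            prev = (uid, off)
        if prev is not None:
            runs[run_uid].append(UnitigRun(run_start, run_lo, prev[1] + 1))
    for rl in runs:
        rl.sort()
    return DBGIndex(k=k, unitigs=unitigs, kmer_map=kmer_map, runs=runs, svref=svref)
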