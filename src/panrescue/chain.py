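"""Sparse dynamic programming chaining of long match blocks.

A block (long seed) is an exact match between a read interval and an
anchor interval.  Blocks on the same anchor and strand are chained with
the recurrence

    f(p) = max( L(p),  max_{q < p} f(q) + L(pq) - theta(p, q) )

where L(pq) is the part of block p that does not overlap block q on the
read, and the gap penalty between chained blocks is

    theta(p, q) = 0.125 * |(refgap) - (readgap)| + 3

i.e. an eighth of the diagonal offset between the two blocks plus a
constant.  The absolute value guards against rewarding misordered
seeds; a transition is refused outright when theta exceeds L(pq)
(chain split), standard chaining practice.
"""

from __future__ import annotations

from dataclasses import dataclass, field


def chain_gap_penalty(delta_ref: int, delta_read: int) -> float:
    """Gap penalty between two chained blocks; 3 at zero diagonal offset."""
    return 0.125 * abs(delta_ref - delta_read) + 3.0


@dataclass(frozen=True)
class ChainSeed:
    """Exact match block: read[read_off:read_off+length] == anchor slice."""

    read_off: int
    length: int
    anchor_id: int
    anchor_off: int
    strand: str = "+"

    @property
    def read_end(self) -> int:
        return self.read_off + self.length

    @property
    def anchor_end(self) -> int:
        return self.anchor_off + self.length


@dataclass
class SeedChain:
    seeds: list[ChainSeed]
    score: float
    anchor_id: int = field(init=False)
    strand: str = field(init=False)

    def __post_init__(self):
        self.anchor_id = self.seeds[0].anchor_id
        self.strand = self.seeds[0].strand

    @property
    def read_span(self) -> tuple[int, int]:
        return (self.seeds[0].read_off, self.seeds[-1].read_end)


def transition_allowed(q: ChainSeed, p: ChainSeed) -> tuple[bool, float, float]:
    """Whether p may extend a chain ending at q; returns (ok, L_pq, theta)."""
    if p.anchor_off <= q.anchor_off or p.read_off <= q.read_off:
        return False, 0.0, 0.0
    l_pq = p.length - max(0, q.read_end - p.read_off)
    if l_pq <= 0:
        return False, 0.0, 0.0
    theta = chain_gap_penalty(p.anchor_off - q.anchor_off, p.read_off - q.read_off)
    if theta > l_pq:
        return False, l_pq, theta
    return True, float(l_pq), theta


def sdp_chain(blocks: list[ChainSeed]) -> list[SeedChain]:
    """Chain blocks per (anchor, strand); return chains ranked by score.

    Backtracking walks parent pointers from high-scoring chain ends;
    blocks already claimed by a better chain terminate the walk, so the
    returned chains are block-disjoint.  Ties rank by lowest anchor_id,
    then leftmost anchor position.
    """
    if not blocks:
        return []
    groups: dict[tuple[int, str], list[ChainSeed]] = {}
    for b in blocks:
        groups.setdefault((b.anchor_id, b.strand), []).append(b)

    entries: list[tuple[float, ChainSeed, dict]] = []
    for _key, grp in sorted(groups.items()):
        grp.sort(key=lambda b: (b.anchor_off, b.read_off))
        f = [float(b.length) for b in grp]
        parent = [-1] * len(grp)
        for p in range(len(grp)):
            for q in range(p):
                ok, l_pq, theta = transition_allowed(grp[q], grp[p])
                if not ok:
                    continue
                cand = f[q] + l_pq - theta
                if cand > f[p]:
                    f[p] = cand
                    parent[p] = q
        for p in range(len(grp)):
            entries.append((f[p], grp[p], {"grp": grp, "parent": parent, "idx": p}))

    entries.sort(key=lambda e: (-e[0], e[1].anchor_id, e[1].anchor_off, e[1].read_off))
    used: set[tuple[int, str, int, int]] = set()
    chains: list[SeedChain] = []
    for score, _blk, ctx in entries:
        grp, parent, idx = ctx["grp"], ctx["parent"], ctx["idx"]
        path = []
        i = idx
        while i != -1:
            b = grp[i]
            key = (b.anchor_id, b.strand, b.anchor_off, b.read_off)
            if key in used:
                break
            path.append(b)
            i = parent[i]
        if not path:
            continue
        for b in path:
            used.add((b.anchor_id, b.strand, b.anchor_off, b.read_off))
        path.reverse()
        chains.append(SeedChain(path, score))
    chains.sort(key=lambda c: (-c.score, c.anchor_id, c.seeds[0].anchor_off))
    return chains
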