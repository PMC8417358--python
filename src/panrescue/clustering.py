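"""Grouping of realigned reads by anchor with top-2 SV retention.

Nearby known SVs often overlap in repeat-rich regions, so reads can be
assigned to the wrong anchor.  SVs whose upstream breakpoint lies
within 50 bp of the running downstream border of a group are greedily
merged; within each group only the two SVs with the most supporting
reads are retained, and reads assigned to the dropped members are
re-assigned to whichever retained anchor shares more distinct k-mers
with the read (seeded random choice on ties).
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass, field

from panrescue.pairing import PairScore
from panrescue.realign import SingleEndAlignment
from panrescue.signals import SignalRead
from panrescue.svref import AnchorSequence, SVReference
from panrescue.util import revcomp

log = logging.getLogger(__name__)

GROUP_DISTANCE = 50


@dataclass
class SVGroup:
    contig: str
    members: list[AnchorSequence]  # sorted by upstream breakpoint
    retained: list[int] = field(default_factory=list)  # anchor ids

    @property
    def interval(self) -> tuple[int, int]:
        return (self.members[0].sv.pos, max(a.sv.end for a in self.members))


@dataclass
class ClusterRead:
    signal: SignalRead
    aln: SingleEndAlignment | None  # None once re-assigned off its anchor
    pair: PairScore
    reassigned: bool = False

    @property
    def new_score(self) -> float:
        return self.aln.score if self.aln is not None else 0.0

    @property
    def orig_score(self) -> float:
        return self.signal.orig.score if self.signal.orig is not None else 0.0

    @property
    def orig_mapq(self) -> int:
        return self.signal.orig.mapq if self.signal.orig is not None else 0


@dataclass
class ReadCluster:
    anchor: AnchorSequence
    reads: list[ClusterRead] = field(default_factory=list)

    @property
    def span(self) -> tuple[int, int]:
        alns = [r.aln for r in self.reads if r.aln is not None]
        if not alns:
            return (0, 0)
        return (min(a.anchor_start for a in alns), max(a.anchor_end for a in alns))


def group_nearby_svs(anchors: list[AnchorSequence], distance: int = GROUP_DISTANCE) -> list[SVGroup]:
    """Greedy left-to-right grouping: join while pos <= border + distance."""
    groups: list[SVGroup] = []
    for a in sorted(anchors, key=lambda x: (x.sv.contig, x.sv.pos, x.anchor_id)):
        if (
            groups
            and groups[-1].contig == a.sv.contig
            and a.sv.pos <= groups[-1].interval[1] + distance
        ):
            groups[-1].members.append(a)
        else:
            groups.append(SVGroup(a.sv.contig, [a]))
    return groups


def select_top2(group: SVGroup, counts: dict[int, int]) -> list[int]:
    """Retain the (up to) two count-maximal members; ties to lower anchor_id."""
    if sum(counts.get(a.anchor_id, 0) for a in group.members) == 0:
        return []
    scored = sorted(
        ((counts.get(a.anchor_id, 0), a.anchor_id) for a in group.members),
        key=lambda t: (-t[0], t[1]),
    )
    return [aid for _cnt, aid in scored[:2]]


def shared_kmer_count(read_seq: str, anchor: AnchorSequence, k: int) -> int:
    """Distinct k-mers of the read present in the anchor (either strand handled upstream)."""
    if len(read_seq) < k or len(anchor.seq) < k:
        return 0
    read_kmers = {read_seq[i : i + k] for i in range(len(read_seq) - k + 1)}
    aseq = anchor.seq
    return sum(1 for km in read_kmers if km in aseq)


def reassign_read(
    read_seq: str,
    a: AnchorSequence,
    b: AnchorSequence,
    k: int,
    rng: random.Random,
) -> int:
    """Choose between two retained anchors by shared distinct k-mer count."""
    ca = shared_kmer_count(read_seq, a, k)
    cb = shared_kmer_count(read_seq, b, k)
    if ca > cb:
        return a.anchor_id
    if cb > ca:
        return b.anchor_id
    return rng.choice([a.anchor_id, b.anchor_id])


def cluster_reads(
    kept: list[tuple[SignalRead, SingleEndAlignment, PairScore]],
    svref: SVReference,
    k: int,
    rng: random.Random,
) -> dict[int, ReadCluster]:
    """Full clustering stage: group SVs, retain top-2, re-assign strays."""
    counts: dict[int, int] = {}
    for _sr, aln, _ps in kept:
        counts[aln.anchor_id] = counts.get(aln.anchor_id, 0) + 1
    groups = group_nearby_svs(svref.anchors)
    clusters: dict[int, ReadCluster] = {}
    retained_of: dict[int, list[int]] = {}
    for g in groups:
        g.retained = select_top2(g, counts)
        for a in g.members:
            retained_of[a.anchor_id] = g.retained
        for aid in g.retained:
            clusters[aid] = ReadCluster(svref.anchor(aid))
    n_reassigned = 0
    for sr, aln, ps in kept:
        retained = retained_of.get(aln.anchor_id, [])
        if not retained:
            continue
        if aln.anchor_id in retained:
            clusters[aln.anchor_id].reads.append(ClusterRead(sr, aln, ps))
            continue
        n_reassigned += 1
        oriented = sr.sequence if aln.strand == "+" else revcomp(sr.sequence)
        if len(retained) == 1:
            target = retained[0]
        else:
            target = reassign_read(
                oriented, svref.anchor(retained[0]), svref.anchor(retained[1]), k, rng
            )
        clusters[target].reads.append(ClusterRead(sr, None, ps, reassigned=True))
    log.info("clustering: %d groups, %d clusters, %d reads re-assigned",
             len(groups), len(clusters), n_reassigned)
    return clusters
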