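"""Pair-level rescoring of realigned read ends.

Both ends of a signal pair carry a short list of candidate single-end
alignments: the realigned placements on SV anchors plus the original
aligner's placement.  The pair score is the exhaustive maximum over all
candidate combinations of s(R1_p) + s(R2_q) plus a bonus K when the two
ends pair properly (opposite orientations, forward mate leftmost,
insert size within mean +/- 1.5 sd).  Because anchor coordinates differ
from genome coordinates by the SV allele length, an original mate
position downstream of the SV breakpoint is offered in two flavours —
unshifted and shifted by the SV length — and either may make the pair
proper.

A pair is kept only when realignment strictly improved it: if the best
combination ties or loses against the best all-original combination,
the pair is recorded as unmapped and dropped from output.
"""

from __future__ import annotations

import logging
import os
import statistics
from dataclasses import dataclass
from typing import Sequence

import pysam

from panrescue.align import cigar_to_ops
from panrescue.realign import SingleEndAlignment
from panrescue.signals import OrigAlignment, SignalRead
from panrescue.svref import SVRecord, SVReference
from panrescue.util import revcomp

log = logging.getLogger(__name__)

DEFAULT_PAIR_BONUS = 50.0
ISIZE_SD_FACTOR = 1.5


@dataclass(frozen=True)
class InsertSizeModel:
    mean: float
    sd: float

    @property
    def interval(self) -> tuple[float, float]:
        half = max(ISIZE_SD_FACTOR * self.sd, 1.0)  # degenerate sd -> +/- 1 bp
        return (self.mean - half, self.mean + half)

    def accepts(self, isize: float) -> bool:
        lo, hi = self.interval
        return lo <= abs(isize) <= hi


def estimate_isize(
    isizes: Sequence[int],
    min_pairs: int = 100,
    fallback: tuple[float, float] = (400.0, 50.0),
) -> InsertSizeModel:
    """Robust insert-size model: median and MAD-scaled sd of |ISIZE|."""
    values = [abs(int(v)) for v in isizes if v]
    if len(values) < min_pairs:
        log.warning("only %d proper pairs for ISIZE estimation; using fallback %s",
                    len(values), fallback)
        return InsertSizeModel(*fallback)
    med = statistics.median(values)
    mad = statistics.median(abs(v - med) for v in values)
    return InsertSizeModel(float(med), 1.4826 * float(mad))


def dual_coordinates(pos: int, sv: SVRecord) -> list[tuple[int, bool]]:
    """Genome-coordinate candidates for a mate's original position.

    Positions downstream of the SV breakpoint additionally get the
    value shifted by the SV length (the deleted sequence is absent from
    / the inserted sequence present in the donor haplotype).
    """
    out = [(pos, False)]
    if sv.svtype == "DEL" and pos > sv.end:
        out.append((pos - sv.svlen, True))
    elif sv.svtype in ("INS", "DUP") and pos > sv.pos:
        out.append((pos + sv.svlen, True))
    return out


@dataclass
class Candidate:
    """One single-end placement: a realigned anchor hit or the original."""

    source: str  # "pan" | "orig"
    score: float
    strand: str
    aln: SingleEndAlignment | None = None  # pan only
    orig: OrigAlignment | None = None  # orig only

    @property
    def anchor_id(self) -> int | None:
        return self.aln.anchor_id if self.aln is not None else None


def _ref_span(cigar: str) -> int:
    return sum(ln for op, ln in cigar_to_ops(cigar) if op in "MDX=") if cigar != "*" else 0


def _pan_genome_span(c: Candidate, svref: SVReference) -> tuple[str, int, int]:
    a = c.aln
    lift_l = svref.lift(a.anchor_id, a.anchor_start)
    lift_r = svref.lift(a.anchor_id, max(a.anchor_start, a.anchor_end - 1))
    return lift_l.contig, lift_l.position, lift_r.position + 1


def _proper(c1: Candidate, c2: Candidate, model: InsertSizeModel, svref: SVReference) -> bool:
    if c1.strand == c2.strand:
        return False
    if c1.source == "pan" and c2.source == "pan":
        a1, a2 = c1.aln, c2.aln
        if a1.anchor_id != a2.anchor_id:
            return False
        left, right = (a1, a2) if a1.anchor_start <= a2.anchor_start else (a2, a1)
        if left.strand != "+":
            return False
        return model.accepts(max(a1.anchor_end, a2.anchor_end) - min(a1.anchor_start, a2.anchor_start))
    if c1.source == "orig" and c2.source == "orig":
        o1, o2 = c1.orig, c2.orig
        if o1.contig != o2.contig:
            return False
        left, right = (o1, o2) if o1.pos <= o2.pos else (o2, o1)
        if left.strand != "+":
            return False
        span = max(o1.pos + _ref_span(o1.cigar), o2.pos + _ref_span(o2.cigar)) - left.pos
        return model.accepts(span)
    pan, orig = (c1, c2) if c1.source == "pan" else (c2, c1)
    sv = svref.anchor(pan.aln.anchor_id).sv
    contig, gstart, gend = _pan_genome_span(pan, svref)
    if contig != orig.orig.contig:
        return False
    ospan = _ref_span(orig.orig.cigar)
    for opos, _shifted in dual_coordinates(orig.orig.pos, sv):
        left_pos, left_strand = (gstart, pan.strand) if gstart <= opos else (opos, orig.strand)
        if left_strand != "+":
            continue
        span = max(gend, opos + ospan) - min(gstart, opos)
        if model.accepts(span):
            return True
    return False


@dataclass
class PairScore:
    score: float
    c1: Candidate | None
    c2: Candidate | None
    proper: bool
    bonus: float

    @property
    def n_pan(self) -> int:
        return sum(1 for c in (self.c1, self.c2) if c is not None and c.source == "pan")


def _combo_rank(ps: PairScore) -> tuple:
    aid = min((c.anchor_id for c in (ps.c1, ps.c2)
               if c is not None and c.anchor_id is not None), default=1 << 30)
    pos = min((c.aln.anchor_start for c in (ps.c1, ps.c2) if c is not None and c.aln),
              default=1 << 30)
    return (-ps.n_pan, aid, pos)


def score_pairings(
    r1: list[Candidate],
    r2: list[Candidate],
    model: InsertSizeModel,
    svref: SVReference,
    bonus: float = DEFAULT_PAIR_BONUS,
) -> PairScore | None:
    """Exhaustive max over all (p, q) combinations; ties prefer realigned ends."""
    combos: list[PairScore] = []
    if r1 and r2:
        for c1 in r1:
            for c2 in r2:
                prop = _proper(c1, c2, model, svref)
                k = bonus if prop else 0.0
                combos.append(PairScore(c1.score + c2.score + k, c1, c2, prop, k))
    elif r1:
        combos = [PairScore(c.score, c, None, False, 0.0) for c in r1]
    elif r2:
        combos = [PairScore(c.score, None, c, False, 0.0) for c in r2]
    if not combos:
        return None
    best = max(combos, key=lambda ps: ps.score)
    ties = [ps for ps in combos if ps.score == best.score]
    ties.sort(key=_combo_rank)
    return ties[0]


def filter_original_best(
    r1: list[Candidate],
    r2: list[Candidate],
    model: InsertSizeModel,
    svref: SVReference,
    bonus: float = DEFAULT_PAIR_BONUS,
) -> PairScore | None:
    """Keep the pair only if realignment strictly beats the original pairing.

    Returns the winning combination, or None when the pair must be
    recorded as unmapped (original-best or tie, or no candidates).
    """
    best = score_pairings(r1, r2, model, svref, bonus)
    if best is None or best.n_pan == 0:
        return None
    o1 = [c for c in r1 if c.source == "orig"]
    o2 = [c for c in r2 if c.source == "orig"]
    orig_best = score_pairings(o1, o2, model, svref, bonus)
    if orig_best is not None and orig_best.score >= best.score:
        return None
    return best


# ---------------------------------------------------------------------------
# SAM output against the SV reference


def emit_sam(
    kept: list[tuple[SignalRead, SingleEndAlignment, PairScore]],
    svref: SVReference,
    path: str | os.PathLike,
    seed: int | None = None,
) -> None:
    """Write kept realigned ends as SAM records on anchor coordinates.

    Records are coordinate-sorted by (anchor, offset); the ``za`` tag
    carries the anchor id and ``zq``/``zs`` preserve the original MAPQ
    and score.
    """
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": a.name, "LN": len(a.seq)} for a in svref.anchors],
        "PG": [{"ID": "panrescue", "PN": "panrescue"}
               | ({"CL": f"seed={seed}"} if seed is not None else {})],
    }
    rows = sorted(kept, key=lambda t: (t[1].anchor_id, t[1].anchor_start, t[0].name, t[0].mate))
    with pysam.AlignmentFile(os.fspath(path), "w", header=header) as out:
        for sr, aln, ps in rows:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = sr.name
            seq = sr.sequence if aln.strand == "+" else revcomp(sr.sequence)
            qual = sr.qualities if aln.strand == "+" else sr.qualities[::-1]
            rec.query_sequence = seq
            rec.query_qualities = pysam.qualitystring_to_array(qual)
            flag = 0x1
            if ps.proper:
                flag |= 0x2
            if aln.strand == "-":
                flag |= 0x10
            flag |= 0x40 if sr.mate == 1 else 0x80
            mate_ps = ps.c2 if sr.mate == 1 else ps.c1
            if mate_ps is None or mate_ps.source != "pan":
                flag |= 0x8
            else:
                if mate_ps.strand == "-":
                    flag |= 0x20
            rec.flag = flag
            rec.reference_id = aln.anchor_id
            rec.reference_start = aln.anchor_start
            rec.mapping_quality = 60
            rec.cigarstring = aln.cigar
            if mate_ps is not None and mate_ps.source == "pan":
                rec.next_reference_id = mate_ps.aln.anchor_id
                rec.next_reference_start = mate_ps.aln.anchor_start
                if mate_ps.aln.anchor_id == aln.anchor_id:
                    rec.template_length = (
                        max(aln.anchor_end, mate_ps.aln.anchor_end)
                        - min(aln.anchor_start, mate_ps.aln.anchor_start)
                    ) * (1 if aln.anchor_start <= mate_ps.aln.anchor_start else -1)
            else:
                rec.next_reference_id = -1
                rec.next_reference_start = -1
            tags = [("za", aln.anchor_id), ("AS", int(aln.score)), ("NM", aln.mismatches)]
            if sr.orig is not None:
                tags += [("zs", int(sr.orig.score)), ("zq", sr.orig.mapq)]
            rec.set_tags(tags)
            out.write(rec)
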