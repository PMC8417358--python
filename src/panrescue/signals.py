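"""Extraction of potential SV-spanning read pairs from original alignments.

A read pair is *perfectly aligned* when both ends are full-length
matches (CIGAR of M/=/X only, no clipping or indels), properly paired,
with at most one mismatch each; such pairs carry no SV signal and are
rejected.  Everything else — clipped, split, discordant, indel-bearing
or unmapped pairs — is extracted together with its original-alignment
metadata and serialized as FASTQ whose comment field round-trips the
metadata exactly.
"""

from __future__ import annotations

import logging
import os
import re
from dataclasses import dataclass
from typing import Iterable

import pysam

from panrescue.align import DEFAULT_SCHEME, ScoringScheme
from panrescue.util import revcomp

log = logging.getLogger(__name__)

_FULL_MATCH_OPS = {0, 7, 8}  # M, =, X


@dataclass
class OrigAlignment:
    contig: str
    pos: int  # 1-based leftmost
    flag: int
    score: float
    cigar: str
    mapq: int
    isize: int
    mismatches: int

    @property
    def is_reverse(self) -> bool:
        return bool(self.flag & 0x10)

    @property
    def strand(self) -> str:
        return "-" if self.is_reverse else "+"

    @property
    def proper(self) -> bool:
        return bool(self.flag & 0x2)


@dataclass
class SignalRead:
    name: str
    sequence: str  # sequencer orientation
    qualities: str
    mate: int  # 1 or 2
    orig: OrigAlignment | None  # None when originally unmapped


@dataclass
class ExtractStats:
    total_pairs: int = 0
    perfect_pairs: int = 0
    emitted_pairs: int = 0
    orphans: int = 0


_MD_MISMATCH = re.compile(r"(\d+)|(\^[A-Z]+)|([A-Z])")


def mismatch_count(read: pysam.AlignedSegment) -> int | None:
    """Mismatches of an aligned record: NM minus indel bases, or MD fallback."""
    indel = sum(ln for op, ln in (read.cigartuples or []) if op in (1, 2))
    if read.has_tag("NM"):
        return max(0, int(read.get_tag("NM")) - indel)
    if read.has_tag("MD"):
        mism = 0
        for m in _MD_MISMATCH.finditer(str(read.get_tag("MD"))):
            if m.group(3):
                mism += 1
        return mism
    return None


def original_score(read: pysam.AlignedSegment, scheme: ScoringScheme = DEFAULT_SCHEME) -> float:
    """AS tag when present, else a score comparable with realignment scores."""
    if read.is_unmapped:
        return 0.0
    if read.has_tag("AS"):
        return float(read.get_tag("AS"))
    mism = mismatch_count(read) or 0
    aligned = sum(ln for op, ln in (read.cigartuples or []) if op in _FULL_MATCH_OPS)
    gaps = [ln for op, ln in (read.cigartuples or []) if op in (1, 2)]
    return float(scheme.read_score(aligned, mism, gaps))


def _full_length(read: pysam.AlignedSegment) -> bool:
    cig = read.cigartuples
    return bool(cig) and all(op in _FULL_MATCH_OPS for op, _ in cig)


def is_perfect_pair(r1: pysam.AlignedSegment, r2: pysam.AlignedSegment) -> bool:
    """True iff both ends are full-length, properly paired, with <=1 mismatch."""
    for r in (r1, r2):
        if r.is_unmapped or not r.is_proper_pair or not _full_length(r):
            return False
        mism = mismatch_count(r)
        if mism is None or mism > 1:
            return False
        if r.has_tag("SA"):  # split alignment
            return False
    return True


def _to_signal(read: pysam.AlignedSegment, scheme: ScoringScheme) -> SignalRead:
    seq = read.query_sequence or ""
    qual = "".join(chr(q + 33) for q in (read.query_qualities or [])) or "I" * len(seq)
    if read.is_reverse:
        seq = revcomp(seq)
        qual = qual[::-1]
    orig = None
    if not read.is_unmapped:
        orig = OrigAlignment(
            contig=read.reference_name,
            pos=read.reference_start + 1,
            flag=read.flag,
            score=original_score(read, scheme),
            cigar=read.cigarstring or "*",
            mapq=read.mapping_quality,
            isize=read.template_length,
            mismatches=mismatch_count(read) or 0,
        )
    return SignalRead(
        name=read.query_name,
        sequence=seq.upper(),
        qualities=qual,
        mate=2 if read.is_read2 else 1,
        orig=orig,
    )


def extract_signal_reads(
    alignment_path: str | os.PathLike,
    scheme: ScoringScheme = DEFAULT_SCHEME,
) -> tuple[list[tuple[SignalRead | None, SignalRead | None]], ExtractStats]:
    """Collect the read pairs failing :func:`is_perfect_pair`.

    Mates are re-paired by name, so both name- and coordinate-sorted
    inputs work.  Orphans (mate never seen) are emitted with the mate
    marked unavailable; fully unmapped pairs are emitted as signatures
    of long novel insertions.
    """
    pending: dict[str, pysam.AlignedSegment] = {}
    pairs: list[tuple[SignalRead | None, SignalRead | None]] = []
    stats = ExtractStats()
    mode = "r" if str(alignment_path).endswith(".sam") else "rb"
    with pysam.AlignmentFile(os.fspath(alignment_path), mode, check_sq=False) as af:
        for read in af:
            if read.is_secondary or read.is_supplementary:
                continue
            if read.is_duplicate or read.is_qcfail:
                continue
            if not read.is_paired:
                stats.orphans += 1
                sr = _to_signal(read, scheme)
                pairs.append((sr, None) if sr.mate == 1 else (None, sr))
                continue
            mate = pending.pop(read.query_name, None)
            if mate is None:
                pending[read.query_name] = read
                continue
            r1, r2 = (mate, read) if mate.is_read1 else (read, mate)
            stats.total_pairs += 1
            if not r1.is_unmapped and not r2.is_unmapped and is_perfect_pair(r1, r2):
                stats.perfect_pairs += 1
                continue
            stats.emitted_pairs += 1
            pairs.append((_to_signal(r1, scheme), _to_signal(r2, scheme)))
    for read in pending.values():
        stats.orphans += 1
        sr = _to_signal(read, scheme)
        pairs.append((sr, None) if sr.mate == 1 else (None, sr))
    log.info(
        "extract: %d pairs seen, %d perfect (rejected), %d emitted, %d orphans",
        stats.total_pairs, stats.perfect_pairs, stats.emitted_pairs, stats.orphans,
    )
    return pairs, stats


# ---------------------------------------------------------------------------
# FASTQ serialization with structured comments


def _comment_of(sr: SignalRead) -> str:
    o = sr.orig
    if o is None:
        return "zp:*"
    return (
        f"zp:{o.contig}:{o.pos} zs:{o.score:g} zc:{o.cigar} zq:{o.mapq} "
        f"zi:{o.isize} zf:{o.flag} zm:{o.mismatches}"
    )


def _parse_comment(comment: str) -> OrigAlignment | None:
    fields = dict(tok.split(":", 1) for tok in comment.split())
    if fields.get("zp", "*") == "*":
        return None
    contig, pos = fields["zp"].rsplit(":", 1)
    return OrigAlignment(
        contig=contig,
        pos=int(pos),
        flag=int(fields.get("zf", 0)),
        score=float(fields.get("zs", 0)),
        cigar=fields.get("zc", "*"),
        mapq=int(fields.get("zq", 0)),
        isize=int(fields.get("zi", 0)),
        mismatches=int(fields.get("zm", 0)),
    )


def write_signal_fastq(
    pairs: Iterable[tuple[SignalRead | None, SignalRead | None]],
    path: str | os.PathLike,
) -> None:
    with open(os.fspath(path), "w") as fq:
        for r1, r2 in pairs:
            for sr in (r1, r2):
                if sr is None:
                    continue
                fq.write(f"@{sr.name}/{sr.mate} {_comment_of(sr)}\n")
                fq.write(sr.sequence + "\n+\n" + sr.qualities + "\n")


def read_signal_fastq(path: str | os.PathLike) -> list[tuple[SignalRead | None, SignalRead | None]]:
    by_name: dict[str, dict[int, SignalRead]] = {}
    order: list[str] = []
    with open(os.fspath(path)) as fq:
        while True:
            header = fq.readline().rstrip("\n")
            if not header:
                break
            seq = fq.readline().rstrip("\n")
            fq.readline()
            qual = fq.readline().rstrip("\n")
            tag, _, comment = header[1:].partition(" ")
            name, mate = tag.rsplit("/", 1)
            sr = SignalRead(name, seq, qual, int(mate), _parse_comment(comment))
            if name not in by_name:
                by_name[name] = {}
                order.append(name)
            by_name[name][sr.mate] = sr
    return [(by_name[n].get(1), by_name[n].get(2)) for n in order]
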