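"""Construction of the SV-anchor pan-genome reference.

Each known structural variant is converted into one linear *anchor
sequence*: for a deletion the two reference flanks around the deleted
interval concatenated directly, for an insertion or duplication the
upstream flank, the inserted allele, and the downstream flank.  The
anchors are concatenated into the *SV reference*, the realignment target
for SV-signature reads, together with a bidirectional coordinate
lift-over between anchor offsets and genome positions.

Coordinate conventions
----------------------
Internally everything is 0-based half-open.  ``SVRecord.pos`` stores the
1-based VCF POS of the padding base, which doubles as the 0-based start
index of the deleted interval (or the 0-based insertion point), so a
deletion removes ``ref[pos:end]`` in 0-based slicing.  Lift-over results
are reported 1-based, matching VCF/SAM output.
"""

from __future__ import annotations

import logging
import os
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pysam

from panrescue.errors import PanrescueError

log = logging.getLogger(__name__)

DEFAULT_FLANK = 250

_SUPPORTED = {"DEL", "INS", "DUP"}


@dataclass(frozen=True)
class SVRecord:
    """One known (or called) structural variant, normalized.

    ``pos`` is the 1-based position of the padding base before the first
    breakpoint; ``end`` the 1-based second breakpoint for deletions and
    equal to ``pos`` for insertions.  For INS/DUP, ``alt_seq`` holds the
    inserted allele and ``len(alt_seq) == svlen``.
    """

    id: str
    contig: str
    pos: int
    end: int
    svtype: str
    svlen: int
    alt_seq: str = ""

    def __post_init__(self):
        if self.svtype not in _SUPPORTED:
            raise PanrescueError(f"unsupported svtype {self.svtype}")
        if self.svlen < 1:
            raise PanrescueError("svlen must be >= 1")
        if self.svtype == "DEL" and self.end - self.pos != self.svlen:
            raise PanrescueError("DEL requires end - pos == svlen")
        if self.svtype in ("INS", "DUP") and len(self.alt_seq) != self.svlen:
            raise PanrescueError("INS/DUP requires len(alt_seq) == svlen")


class LiftResult(NamedTuple):
    contig: str
    position: int  # 1-based genome coordinate
    shifted: bool  # downstream of the SV allele
    inserted: bool  # inside an inserted allele (no unique genome base)


@dataclass
class AnchorSequence:
    """Anchor string for one SV plus the flank bookkeeping for lift-over."""

    anchor_id: int
    sv: SVRecord
    seq: str
    upstream_len: int
    downstream_len: int
    short: bool = False  # anchor shorter than one read length

    @property
    def insert_len(self) -> int:
        return len(self.seq) - self.upstream_len - self.downstream_len

    @property
    def insert_span(self) -> tuple[int, int]:
        """Half-open interval of the inserted allele within ``seq``."""
        return (self.upstream_len, self.upstream_len + self.insert_len)

    @property
    def name(self) -> str:
        return f"anchor_{self.anchor_id}"

    def lift(self, offset: int) -> LiftResult:
        sv = self.sv
        if not 0 <= offset < len(self.seq):
            raise PanrescueError(
                f"offset {offset} out of range for anchor {self.anchor_id}"
            )
        up = self.upstream_len
        ins_lo, ins_hi = self.insert_span
        if offset < up:
            g0 = sv.pos - up + offset
            return LiftResult(sv.contig, g0 + 1, False, False)
        if offset < ins_hi:
            return LiftResult(sv.contig, sv.pos, False, True)
        j = offset - ins_hi
        base = sv.end if sv.svtype == "DEL" else sv.pos
        return LiftResult(sv.contig, base + j + 1, True, False)

    def anchor_offset_of(self, position: int) -> int | None:
        """Inverse lift for flank bases: 1-based genome position -> offset."""
        sv = self.sv
        g0 = position - 1
        up_start = sv.pos - self.upstream_len
        if up_start <= g0 < sv.pos:
            return g0 - up_start
        base = sv.end if sv.svtype == "DEL" else sv.pos
        if base <= g0 < base + self.downstream_len:
            return self.insert_span[1] + (g0 - base)
        return None


def _contig_seq(ref: Mapping[str, str], contig: str) -> str:
    seq = ref[contig]
    return str(seq).upper()


def build_deletion_anchor(
    ref: Mapping[str, str], sv: SVRecord, flank: int = DEFAULT_FLANK, anchor_id: int = 0
) -> AnchorSequence:
    """Anchor = upstream flank + downstream flank, skipping the deleted bases."""
    if sv.svtype != "DEL":
        raise PanrescueError("build_deletion_anchor requires a DEL record")
    seq = _contig_seq(ref, sv.contig)
    if not (0 <= sv.pos <= sv.end <= len(seq)):
        raise PanrescueError(f"breakpoints of {sv.id} outside contig {sv.contig}")
    up = seq[max(0, sv.pos - flank) : sv.pos]
    down = seq[sv.end : sv.end + flank]
    return AnchorSequence(anchor_id, sv, up + down, len(up), len(down))


def build_insertion_anchor(
    ref: Mapping[str, str], sv: SVRecord, flank: int = DEFAULT_FLANK, anchor_id: int = 0
) -> AnchorSequence:
    """Anchor = upstream flank + inserted allele + downstream flank."""
    if sv.svtype not in ("INS", "DUP"):
        raise PanrescueError("build_insertion_anchor requires an INS/DUP record")
    if not sv.alt_seq:
        raise PanrescueError(f"insertion {sv.id} has empty allele")
    seq = _contig_seq(ref, sv.contig)
    if not (0 <= sv.pos <= len(seq)):
        raise PanrescueError(f"breakpoint of {sv.id} outside contig {sv.contig}")
    up = seq[max(0, sv.pos - flank) : sv.pos]
    down = seq[sv.pos : sv.pos + flank]
    return AnchorSequence(
        anchor_id, sv, up + sv.alt_seq.upper() + down, len(up), len(down)
    )


def build_anchor(
    ref: Mapping[str, str], sv: SVRecord, flank: int = DEFAULT_FLANK, anchor_id: int = 0
) -> AnchorSequence:
    if sv.svtype == "DEL":
        return build_deletion_anchor(ref, sv, flank, anchor_id)
    return build_insertion_anchor(ref, sv, flank, anchor_id)


@dataclass
class SVReference:
    """Concatenation of all anchors with coordinate lift-over maps."""

    anchors: list[AnchorSequence]
    flank: int = DEFAULT_FLANK
    concat_seq: str = field(init=False)
    offsets: dict[int, int] = field(init=False)

    def __post_init__(self):
        self.offsets = {}
        parts = []
        off = 0
        for a in self.anchors:
            self.offsets[a.anchor_id] = off
            parts.append(a.seq)
            off += len(a.seq)
        self.concat_seq = "".join(parts)
        self._starts = sorted(self.offsets.values())
        self._ids_by_start = [
            aid for aid, _ in sorted(self.offsets.items(), key=lambda kv: kv[1])
        ]

    def anchor(self, anchor_id: int) -> AnchorSequence:
        return self.anchors[anchor_id]

    def anchor_at(self, concat_pos: int) -> tuple[int, int]:
        """Map a position in ``concat_seq`` to (anchor_id, offset)."""
        i = bisect_right(self._starts, concat_pos) - 1
        aid = self._ids_by_start[i]
        return aid, concat_pos - self._starts[i]

    def lift(self, anchor_id: int, offset: int) -> LiftResult:
        return self.anchors[anchor_id].lift(offset)


def lift_to_genome(svref: SVReference, anchor_id: int, offset: int) -> LiftResult:
    return svref.lift(anchor_id, offset)


def dedupe_svs(svs: Iterable[SVRecord]) -> list[SVRecord]:
    """Drop exact duplicates (same type, contig, pos, svlen), keeping the first."""
    seen = set()
    out = []
    for sv in svs:
        key = (sv.svtype, sv.contig, sv.pos, sv.svlen)
        if key in seen:
            continue
        seen.add(key)
        out.append(sv)
    return out


def build_sv_reference(
    svs: list[SVRecord],
    ref: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    min_anchor_len: int = 150,
) -> SVReference:
    if not svs:
        raise PanrescueError("no usable SV records")
    svs = dedupe_svs(sorted(svs, key=lambda s: (s.contig, s.pos, s.svlen)))
    anchors = []
    for i, sv in enumerate(svs):
        a = build_anchor(ref, sv, flank, anchor_id=i)
        if len(a.seq) < min_anchor_len:
            a.short = True
            log.warning("anchor %d (%s) shorter than a read (%d bp)", i, sv.id, len(a.seq))
        anchors.append(a)
    return SVReference(anchors, flank=flank)


# ---------------------------------------------------------------------------
# VCF parsing


_ALLELE_CHARS = set("ACGTN")


def _explicit_record(rec, ref_allele: str, alt: str, contig: str, rid: str):
    if not set(alt) <= _ALLELE_CHARS:  # breakend or other non-sequence ALT
        return None
    if len(ref_allele) > 1 and len(alt) == 1 and ref_allele[0] == alt[0]:
        svlen = len(ref_allele) - 1
        return SVRecord(rid, contig, rec.pos, rec.pos + svlen, "DEL", svlen)
    if len(alt) > 1 and len(ref_allele) == 1 and alt[0] == ref_allele[0]:
        ins = alt[1:].upper()
        svtype = str(rec.info.get("SVTYPE", "INS")) if "SVTYPE" in rec.info else "INS"
        if svtype not in ("INS", "DUP"):
            svtype = "INS"
        return SVRecord(rid, contig, rec.pos, rec.pos, svtype, len(ins), ins)
    return None


def parse_sv_vcf(vcf_path: str | os.PathLike, reference: Mapping[str, str]) -> list[SVRecord]:
    """Normalize a known-SV VCF into :class:`SVRecord` objects.

    Explicit REF/ALT alleles and symbolic ``<DEL>``/``<INS>``/``<DUP>``
    ALTs (with END/SVLEN and, for insertions, a SEQ-style INFO key) are
    accepted.  BND/INV and otherwise unusable records are skipped with a
    logged count; duplications become insertions of the duplicated
    reference segment at the duplication end breakpoint.
    """
    records: list[SVRecord] = []
    skipped = 0
    with pysam.VariantFile(os.fspath(vcf_path)) as vf:
        for i, rec in enumerate(vf):
            rid = rec.id or f"sv{i}"
            contig = rec.contig
            if contig not in reference:
                log.warning("record %s: contig %s not in reference, skipped", rid, contig)
                skipped += 1
                continue
            if not rec.alts:
                skipped += 1
                continue
            alt = rec.alts[0]
            try:
                if alt.startswith("<"):
                    sv = _symbolic_record(rec, alt, contig, rid, reference)
                else:
                    sv = _explicit_record(rec, rec.ref.upper(), alt.upper(), contig, rid)
            except PanrescueError as exc:
                log.warning("record %s skipped: %s", rid, exc)
                sv = None
            if sv is None:
                skipped += 1
                continue
            contig_len = len(reference[contig])
            if sv.end > contig_len or sv.pos > contig_len:
                log.warning("record %s: breakpoints outside contig, skipped", rid)
                skipped += 1
                continue
            records.append(sv)
    if skipped:
        log.info("parse_sv_vcf: %d records skipped, %d usable", skipped, len(records))
    return records


def _symbolic_record(rec, alt: str, contig: str, rid: str, reference):
    svtype = alt.strip("<>").split(":")[0]
    if svtype == "DEL":
        svlen = rec.stop - rec.pos
        if svlen < 1 and "SVLEN" in rec.info:
            raw = rec.info["SVLEN"]
            svlen = abs(int(raw[0] if isinstance(raw, tuple) else raw))
        if svlen < 1:
            raise PanrescueError("symbolic DEL without END/SVLEN")
        return SVRecord(rid, contig, rec.pos, rec.pos + svlen, "DEL", svlen)
    if svtype == "DUP":
        seg = str(reference[contig])[rec.pos : rec.stop].upper()
        if not seg:
            raise PanrescueError("symbolic DUP with empty span")
        return SVRecord(rid, contig, rec.stop, rec.stop, "DUP", len(seg), seg)
    if svtype == "INS":
        seq = None
        for key in ("SEQ", "SVINSSEQ", "INSSEQ"):
            if key in rec.info:
                raw = rec.info[key]
                seq = raw[0] if isinstance(raw, tuple) else raw
                break
        if not seq:
            raise PanrescueError("symbolic INS with no sequence available")
        seq = str(seq).upper()
        return SVRecord(rid, contig, rec.pos, rec.pos, "INS", len(seq), seq)
    raise PanrescueError(f"unsupported symbolic type {svtype}")


# ---------------------------------------------------------------------------
# Serialization: FASTA + run-length-encoded lift-over sidecar


def write_sv_reference(svref: SVReference, outdir: str | os.PathLike) -> None:
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "svref.fa"), "w") as fa:
        for a in svref.anchors:
            fa.write(f">{a.name}\n")
            for i in range(0, len(a.seq), 70):
                fa.write(a.seq[i : i + 70] + "\n")
    with open(os.path.join(outdir, "liftover.tsv"), "w") as lo:
        lo.write("#anchor_id\tanchor_start\trun_length\tcontig\tgenome_start\tshifted\tinserted\n")
        for a in svref.anchors:
            runs = []
            if a.upstream_len:
                runs.append((0, a.upstream_len, a.lift(0).position, 0, 0))
            lo_i, hi_i = a.insert_span
            if hi_i > lo_i:
                runs.append((lo_i, hi_i - lo_i, a.sv.pos, 0, 1))
            if a.downstream_len:
                runs.append((hi_i, a.downstream_len, a.lift(hi_i).position, 1, 0))
            for start, length, gpos, sh, ins in runs:
                lo.write(f"{a.anchor_id}\t{start}\t{length}\t{a.sv.contig}\t{gpos}\t{sh}\t{ins}\n")
    with open(os.path.join(outdir, "svrecords.tsv"), "w") as sf:
        sf.write("#anchor_id\tsv_id\tcontig\tpos\tend\tsvtype\tsvlen\talt_seq\n")
        for a in svref.anchors:
            sv = a.sv
            sf.write(
                f"{a.anchor_id}\t{sv.id}\t{sv.contig}\t{sv.pos}\t{sv.end}\t"
                f"{sv.svtype}\t{sv.svlen}\t{sv.alt_seq or '.'}\n"
            )
    with open(os.path.join(outdir, "meta.tsv"), "w") as mf:
        mf.write(f"flank\t{svref.flank}\n")


def load_sv_reference(indir: str | os.PathLike) -> SVReference:
    indir = os.fspath(indir)
    seqs: dict[str, str] = {}
    name = None
    parts: list[str] = []
    with open(os.path.join(indir, "svref.fa")) as fa:
        for line in fa:
            line = line.rstrip()
            if line.startswith(">"):
                if name is not None:
                    seqs[name] = "".join(parts)
                name = line[1:].split()[0]
                parts = []
            else:
                parts.append(line)
        if name is not None:
            seqs[name] = "".join(parts)
    flank = DEFAULT_FLANK
    meta = os.path.join(indir, "meta.tsv")
    if os.path.exists(meta):
        with open(meta) as mf:
            for line in mf:
                key, val = line.split("\t")
                if key == "flank":
                    flank = int(val)
    updown: dict[int, dict[str, int]] = {}
    with open(os.path.join(indir, "liftover.tsv")) as lo:
        for line in lo:
            if line.startswith("#"):
                continue
            aid, start, length, _contig, _gpos, shifted, inserted = line.rstrip("\n").split("\t")
            d = updown.setdefault(int(aid), {"up": 0, "down": 0})
            if int(inserted):
                continue
            d["down" if int(shifted) else "up"] = int(length)
    anchors = []
    with open(os.path.join(indir, "svrecords.tsv")) as sf:
        for line in sf:
            if line.startswith("#"):
                continue
            aid, svid, contig, pos, end, svtype, svlen, alt = line.rstrip("\n").split("\t")
            aid = int(aid)
            sv = SVRecord(svid, contig, int(pos), int(end), svtype, int(svlen),
                          "" if alt == "." else alt)
            seq = seqs[f"anchor_{aid}"]
            a = AnchorSequence(aid, sv, seq, updown[aid]["up"], updown[aid]["down"])
            if len(a.seq) != a.upstream_len + a.insert_len + a.downstream_len:
                raise PanrescueError(f"inconsistent sidecar for anchor {aid}")
            anchors.append(a)
    anchors.sort(key=lambda a: a.anchor_id)
    return SVReference(anchors, flank=flank)
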