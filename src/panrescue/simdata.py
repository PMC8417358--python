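"""Deterministic synthetic worlds for every pipeline stage.

The generator emulates the evaluation design the caller is built for: a
random genome (optionally with tandem-repeat tracts), a donor carrying
implanted heterozygous/homozygous SVs, a *known panel* that is a
jittered, sequence-diverged and optionally subset copy of the truth
(population divergence plus leave-one-out), paired-end reads drawn from
the two donor haplotypes, and an original-style alignment file produced
by a bundled naive aligner that soft-clips across implanted breakpoints
and leaves reads inside long novel insertions unmapped — exactly the
signature classes the extractor consumes.

The companion aligner is intentionally simple (ground-truth anchored
projection plus clipping); it exists to produce realistic
original-alignment metadata, not to be a real aligner.  Sequencing
errors are substitution-only and fragment lengths are drawn from a
normal truncated at +/-3 sd, which keeps the perfect-pair definition
crisp.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pysam

from panrescue.align import DEFAULT_SCHEME
from panrescue.errors import PanrescueError
from panrescue.svref import SVRecord

BASES = np.array(list("ACGT"))
CONTIG = "chr1"


@dataclass
class SimConfig:
    seed: int
    genome_length: int = 200_000
    gc: float = 0.5
    repeats: list = field(default_factory=list)  # [(unit, copies, count)]
    n_svs: int = 20
    sv_len_range: tuple[int, int] = (60, 1000)
    sv_types: tuple[str, ...] = ("DEL", "INS")
    read_length: int = 150
    insert_mean: float = 400.0
    insert_sd: float = 50.0
    depth: float = 30.0
    error_rate: float = 0.002
    jitter: int = 10
    divergence: float = 0.02
    leave_out: float = 0.0

    def __post_init__(self):
        for name, rate in (("gc", self.gc), ("error_rate", self.error_rate),
                           ("divergence", self.divergence), ("leave_out", self.leave_out)):
            if not 0.0 <= rate <= 1.0:
                raise PanrescueError(f"{name} must be within [0, 1]")
        if self.seed is None:
            raise PanrescueError("seed is mandatory")


def _rng(cfg: SimConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng((cfg.seed * 1_000_003 + salt) % (2**31))


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(BASES[rng.choice(4, size=n, p=p)])


def simulate_genome(cfg: SimConfig) -> dict[str, str]:
    """Random genome at the requested GC with optional repeat tracts inserted."""
    rng = _rng(cfg, 1)
    seq = _random_seq(rng, cfg.genome_length, cfg.gc)
    tracts = []
    for unit, copies, count in cfg.repeats:
        for _ in range(count):
            tracts.append(unit * copies)
    if tracts:
        lo, hi = 1000, max(1001, cfg.genome_length - 1000)
        positions = sorted(rng.integers(lo, hi, size=len(tracts)).tolist(), reverse=True)
        for pos, tract in zip(positions, tracts):
            seq = seq[:pos] + tract + seq[pos:]
    return {CONTIG: seq}


@dataclass
class TruthSV:
    sv: SVRecord
    genotype: str  # "0/1" or "1/1"


def implant_svs(genome: dict[str, str], cfg: SimConfig) -> list[TruthSV]:
    """Choose non-overlapping SVs (>=1 kb separation) and their genotypes."""
    rng = _rng(cfg, 2)
    seq = genome[CONTIG]
    n = cfg.n_svs
    truth: list[TruthSV] = []
    lo_len, hi_len = cfg.sv_len_range
    taken: list[tuple[int, int]] = []
    attempts = 0
    while len(truth) < n and attempts < 50 * n:
        attempts += 1
        svlen = int(rng.integers(lo_len, hi_len + 1))
        pos = int(rng.integers(2000, len(seq) - 2000 - svlen))
        if any(pos - 1000 < e and pos + svlen + 1000 > s for s, e in taken):
            continue
        i = len(truth)
        svtype = cfg.sv_types[i % len(cfg.sv_types)]
        if svtype == "DEL":
            sv = SVRecord(f"truth{i}", CONTIG, pos, pos + svlen, "DEL", svlen)
            taken.append((pos - 1000, pos + svlen + 1000))
        else:
            allele = _random_seq(rng, svlen, cfg.gc)
            sv = SVRecord(f"truth{i}", CONTIG, pos, pos, "INS", svlen, allele)
            taken.append((pos - 1000, pos + 1000))
        truth.append(TruthSV(sv, "0/1" if i % 2 else "1/1"))
    truth.sort(key=lambda t: t.sv.pos)
    if len(truth) < n:
        raise PanrescueError("could not place all SVs; genome too small")
    return truth


@dataclass
class Haplotype:
    name: str
    seq: str
    # (hap_start, hap_end, ref_start | None); None marks inserted sequence
    segments: list[tuple[int, int, int | None]]


def build_haplotype(genome: dict[str, str], svs: list[SVRecord], name: str) -> Haplotype:
    """Apply SVs to the reference, keeping a donor->reference segment map."""
    ref = genome[CONTIG]
    parts: list[str] = []
    segments: list[tuple[int, int, int | None]] = []
    cursor = 0  # reference coordinate
    hap_pos = 0
    for sv in sorted(svs, key=lambda s: s.pos):
        if sv.pos < cursor:
            raise PanrescueError("overlapping SVs in haplotype construction")
        chunk = ref[cursor : sv.pos]
        if chunk:
            segments.append((hap_pos, hap_pos + len(chunk), cursor))
            parts.append(chunk)
            hap_pos += len(chunk)
        if sv.svtype == "DEL":
            cursor = sv.end
        else:
            segments.append((hap_pos, hap_pos + sv.svlen, None))
            parts.append(sv.alt_seq)
            hap_pos += sv.svlen
            cursor = sv.pos
    chunk = ref[cursor:]
    if chunk:
        segments.append((hap_pos, hap_pos + len(chunk), cursor))
        parts.append(chunk)
    return Haplotype(name, "".join(parts), segments)


def make_known_panel(truth: list[TruthSV], genome: dict[str, str], cfg: SimConfig) -> list[SVRecord]:
    """Jittered / diverged / subset copy of the truth set.

    Breakpoints shift by up to ``jitter`` bp (same svlen), inserted
    alleles are mutated by substitutions at the divergence rate, and a
    ``leave_out`` fraction of records is removed.
    """
    rng = _rng(cfg, 3)
    seq = genome[CONTIG]
    keep_mask = rng.random(len(truth)) >= cfg.leave_out
    panel: list[SVRecord] = []
    for keep, t in zip(keep_mask, truth):
        if not keep:
            continue
        sv = t.sv
        delta = int(rng.integers(-cfg.jitter, cfg.jitter + 1)) if cfg.jitter else 0
        pos = max(1, min(len(seq) - sv.svlen - 1, sv.pos + delta))
        if sv.svtype == "DEL":
            panel.append(SVRecord(f"panel_{sv.id}", sv.contig, pos, pos + sv.svlen,
                                  "DEL", sv.svlen))
        else:
            allele = list(sv.alt_seq)
            if cfg.divergence > 0:
                hits = np.flatnonzero(rng.random(len(allele)) < cfg.divergence)
                for i in hits:
                    cur = allele[i]
                    allele[i] = str(rng.choice([b for b in "ACGT" if b != cur]))
            panel.append(SVRecord(f"panel_{sv.id}", sv.contig, pos, pos,
                                  "INS", len(allele), "".join(allele)))
    return panel


def write_vcf_records(
    records: list[SVRecord],
    genome: dict[str, str],
    path: str | os.PathLike,
    genotypes: list[str] | None = None,
) -> None:
    """Explicit-allele VCF for truth or panel sets."""
    with open(os.fspath(path), "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for name, seq in genome.items():
            out.write(f"##contig=<ID={name},length={len(seq)}>\n")
        out.write('##INFO=<ID=SVTYPE,Number=1,Type=String,Description="SV type">\n')
        out.write('##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="SV length">\n')
        out.write('##INFO=<ID=END,Number=1,Type=Integer,Description="SV end">\n')
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        cols = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO"
        if genotypes is not None:
            cols += "\tFORMAT\tSAMPLE"
        out.write(cols + "\n")
        for i, sv in enumerate(records):
            seq = genome[sv.contig]
            pad = seq[sv.pos - 1]
            if sv.svtype == "DEL":
                ref, alt = pad + seq[sv.pos : sv.end], pad
                svlen = -sv.svlen
            else:
                ref, alt = pad, pad + sv.alt_seq
                svlen = sv.svlen
            info = f"SVTYPE={sv.svtype};SVLEN={svlen};END={sv.end}"
            row = f"{sv.contig}\t{sv.pos}\t{sv.id}\t{ref}\t{alt}\t.\tPASS\t{info}"
            if genotypes is not None:
                row += f"\tGT\t{genotypes[i]}"
            out.write(row + "\n")


def write_fasta(genome: dict[str, str], path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as out:
        for name, seq in genome.items():
            out.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                out.write(seq[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# Read simulation + naive companion aligner

_COMP = str.maketrans("ACGTN", "TGCAN")


def _rc(s: str) -> str:
    return s.translate(_COMP)[::-1]


@dataclass
class SimRead:
    name: str
    mate: int
    seq: str  # sequencer orientation
    hap: Haplotype
    hap_start: int
    hap_end: int
    reverse: bool  # aligned orientation on the donor haplotype


def _apply_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if hits.size == 0:
        return seq
    out = list(seq)
    for i in hits:
        cur = out[i]
        out[i] = str(rng.choice([b for b in "ACGT" if b != cur]))
    return "".join(out)


def simulate_read_pairs(haplotypes: list[Haplotype], cfg: SimConfig) -> list[tuple[SimRead, SimRead]]:
    rng = _rng(cfg, 4)
    rl = cfg.read_length
    ref_len = cfg.genome_length
    n_total = int(round(cfg.depth * ref_len / (2 * rl)))
    pairs: list[tuple[SimRead, SimRead]] = []
    serial = 0
    per_hap = [n_total // len(haplotypes)] * len(haplotypes)
    per_hap[0] += n_total - sum(per_hap)
    for hap, n in zip(haplotypes, per_hap):
        L = len(hap.seq)
        frags = rng.normal(cfg.insert_mean, cfg.insert_sd, size=n)
        frags = np.clip(frags, cfg.insert_mean - 3 * cfg.insert_sd,
                        cfg.insert_mean + 3 * cfg.insert_sd)
        frags = np.maximum(frags, rl + 2).astype(int)
        starts = rng.integers(0, np.maximum(1, L - frags), size=n)
        for s, f in zip(starts.tolist(), frags.tolist()):
            e = s + f
            r1 = _apply_errors(hap.seq[s : s + rl], rng, cfg.error_rate)
            r2 = _apply_errors(_rc(hap.seq[e - rl : e]), rng, cfg.error_rate)
            name = f"sim{serial}"
            serial += 1
            pairs.append(
                (
                    SimRead(name, 1, r1, hap, s, s + rl, reverse=False),
                    SimRead(name, 2, r2, hap, e - rl, e, reverse=True),
                )
            )
    return pairs


def _project(read: SimRead, min_anchor: int = 20):
    """Project a donor-haplotype read onto the reference via the segment map.

    Returns (ref_pos0, clip_left, match_len, clip_right) or None when
    unmapped (no reference segment overlaps the read by >= min_anchor).
    """
    best = None
    for h0, h1, r0 in read.hap.segments:
        if r0 is None:
            continue
        ov0, ov1 = max(read.hap_start, h0), min(read.hap_end, h1)
        if ov1 - ov0 < min_anchor:
            continue
        if best is None or (ov1 - ov0) > best[0]:
            best = (ov1 - ov0, ov0, ov1, r0 + (ov0 - h0))
    if best is None:
        return None
    _, ov0, ov1, rpos = best
    return rpos, ov0 - read.hap_start, ov1 - ov0, read.hap_end - ov1


def write_alignments(
    pairs: list[tuple[SimRead, SimRead]],
    genome: dict[str, str],
    cfg: SimConfig,
    sam_path: str | os.PathLike,
) -> None:
    """Original-style coordinate-sorted SAM from the naive aligner."""
    ref = genome[CONTIG]
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CONTIG, "LN": len(ref)}],
    }
    scheme = DEFAULT_SCHEME
    rows = []
    for r1, r2 in pairs:
        p1, p2 = _project(r1), _project(r2)
        recs = []
        for read, proj, mate_proj in ((r1, p1, p2), (r2, p2, p1)):
            oriented = _rc(read.seq) if read.reverse else read.seq
            rec = {
                "name": read.name,
                "mate": read.mate,
                "seq": oriented,  # aligned orientation
                "reverse": read.reverse,
                "proj": proj,
                "mate_proj": mate_proj,
                "mate_reverse": (r2 if read.mate == 1 else r1).reverse,
            }
            recs.append(rec)
        rows.append(recs)

    with pysam.AlignmentFile(os.fspath(sam_path), "w", header=header) as out:
        flat = []
        for recs in rows:
            proper = True
            positions = []
            for rec in recs:
                proj = rec["proj"]
                if proj is None or proj[1] or proj[3]:
                    proper = False
                if proj is not None:
                    positions.append(proj[0])
            if len(positions) == 2:
                lo = min(positions)
                hi = max(positions[0] + (recs[0]["proj"][2] if recs[0]["proj"] else 0),
                         positions[1] + (recs[1]["proj"][2] if recs[1]["proj"] else 0))
                tlen = hi - lo
                if not (cfg.insert_mean - 4 * cfg.insert_sd
                        <= tlen
                        <= cfg.insert_mean + 4 * cfg.insert_sd):
                    proper = False
                fwd_first = (recs[0]["proj"][0] <= recs[1]["proj"][0]) == (not recs[0]["reverse"])
                if recs[0]["reverse"] == recs[1]["reverse"] or not fwd_first:
                    proper = False
            else:
                proper = False
                tlen = 0
            for rec, other in ((recs[0], recs[1]), (recs[1], recs[0])):
                a = pysam.AlignedSegment(out.header)
                a.query_name = rec["name"]
                flag = 0x1 | (0x40 if rec["mate"] == 1 else 0x80)
                proj = rec["proj"]
                if rec["reverse"]:
                    flag |= 0x10
                if other["reverse"]:
                    flag |= 0x20
                if proj is None:
                    flag |= 0x4
                if other["proj"] is None:
                    flag |= 0x8
                if proper and proj is not None:
                    flag |= 0x2
                a.flag = flag
                a.query_sequence = rec["seq"]
                a.query_qualities = pysam.qualitystring_to_array("I" * len(rec["seq"]))
                if proj is not None:
                    # aligned orientation equals donor-forward orientation, so
                    # the haplotype-space clips carry over unchanged
                    rpos, cl, ml, cr = proj
                    a.reference_id = 0
                    a.reference_start = rpos
                    a.mapping_quality = 60
                    cigar = []
                    if cl:
                        cigar.append((4, cl))
                    cigar.append((0, ml))
                    if cr:
                        cigar.append((4, cr))
                    a.cigartuples = cigar
                    seg = rec["seq"]
                    # mismatches within the aligned portion
                    off = cigar[0][1] if cigar[0][0] == 4 else 0
                    aligned = seg[off : off + ml]
                    refseg = ref[rpos : rpos + ml]
                    nm = sum(1 for x, y in zip(aligned, refseg) if x != y)
                    a.set_tags([("NM", nm), ("AS", int(scheme.read_score(ml, nm)))])
                else:
                    a.reference_id = 0 if other["proj"] is not None else -1
                    a.reference_start = other["proj"][0] if other["proj"] is not None else -1
                    a.mapping_quality = 0
                if other["proj"] is not None:
                    a.next_reference_id = 0
                    a.next_reference_start = other["proj"][0]
                else:
                    a.next_reference_id = a.reference_id
                    a.next_reference_start = a.reference_start
                if proj is not None and other["proj"] is not None:
                    sign = 1 if proj[0] <= other["proj"][0] else -1
                    a.template_length = sign * tlen
                flat.append(a)
        flat.sort(key=lambda a: (a.reference_id == -1, a.reference_start, a.query_name,
                                 bool(a.flag & 0x80)))
        for a in flat:
            out.write(a)


def write_fastqs(pairs, path1, path2) -> None:
    with open(os.fspath(path1), "w") as f1, open(os.fspath(path2), "w") as f2:
        for r1, r2 in pairs:
            f1.write(f"@{r1.name}/1\n{r1.seq}\n+\n{'I' * len(r1.seq)}\n")
            f2.write(f"@{r2.name}/2\n{r2.seq}\n+\n{'I' * len(r2.seq)}\n")


@dataclass
class SimWorld:
    cfg: SimConfig
    genome: dict[str, str]
    truth: list[TruthSV]
    panel: list[SVRecord]
    haplotypes: list[Haplotype]
    paths: dict[str, str]


def simulate(cfg: SimConfig, outdir: str | os.PathLike) -> SimWorld:
    """Generate the full fixture set: FASTA, truth/panel VCF, FASTQ, SAM."""
    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    genome = simulate_genome(cfg)
    truth = implant_svs(genome, cfg)
    hap_a = build_haplotype(genome, [t.sv for t in truth], "hapA")
    hap_b = build_haplotype(genome, [t.sv for t in truth if t.genotype == "1/1"], "hapB")
    panel = make_known_panel(truth, genome, cfg)
    pairs = simulate_read_pairs([hap_a, hap_b], cfg)
    paths = {
        "ref": os.path.join(outdir, "ref.fa"),
        "truth": os.path.join(outdir, "truth.vcf"),
        "panel": os.path.join(outdir, "panel.vcf"),
        "fq1": os.path.join(outdir, "reads_1.fq"),
        "fq2": os.path.join(outdir, "reads_2.fq"),
        "sam": os.path.join(outdir, "orig.sam"),
    }
    write_fasta(genome, paths["ref"])
    write_vcf_records([t.sv for t in truth], genome, paths["truth"],
                      genotypes=[t.genotype for t in truth])
    if panel:
        write_vcf_records(panel, genome, paths["panel"])
    else:
        write_vcf_records([], genome, paths["panel"])
    write_fastqs(pairs, paths["fq1"], paths["fq2"])
    write_alignments(pairs, genome, cfg, paths["sam"])
    return SimWorld(cfg, genome, truth, panel, [hap_a, hap_b], paths)
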