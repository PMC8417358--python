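# Methods

This note documents the model and the numerical choices behind `panrescue`,
in the spirit of a methods supplement: what each stage assumes, which
parameters matter, and what the synthetic evaluation does and does not
establish.

## The anchor model

A known SV is represented as one linear haplotype fragment ("anchor"):

* deletion — `ref[pos−f .. pos) + ref[end .. end+f)`;
* insertion/duplication — `ref[pos−f .. pos) + allele + ref[pos .. pos+f)`,

with flank `f = 250` bp (long enough that a mainstream short read falls
entirely inside an anchor). Duplications are materialized as insertions of
the duplicated reference segment at the end breakpoint — the novel junction
a read can actually observe. Flanks truncate at contig ends; anchors shorter
than one read length are kept but flagged. Identical records (type, contig,
position, length) are deduplicated at build time, since duplicate anchors
only split read support.

Coordinates are 0-based half-open internally; VCF/SAM output is 1-based.
The lift-over maps every flank base to its unique genome base (injective,
round-trips exactly; property-tested), and every inserted base to the
breakpoint with an `inserted` flag. Downstream-flank coordinates carry a
`shifted` flag: a genome position downstream of the SV corresponds to two
donor coordinates, raw and shifted by the SV length, and pairing uses both.

## Index and realignment

The concatenated anchors are indexed by a de Bruijn graph with k = 22:
maximal non-branching paths (unitigs) are materialized, each k-mer maps to a
unique (unitig, offset), and unitigs carry their occurrence runs in the
reference. Runs record the covered offset interval, so lookups stay exact
when a unitig is clipped at an anchor boundary or an ambiguous base
(`N` breaks unitigs and is never indexed). k is bounded to [8, 31]
(word-packing bound); only the forward strand is indexed and reads are
queried in both orientations.

Seeding uses *unique* k-mers — occurrence count ≤ `max_occ` (default 4) in
the SV reference — plus the first and last k-mer of the read regardless of
repetitiveness, so reads lying wholly inside tandem repeats still seed at
their ends. Seed length equals the index k: a hash-based index cannot answer
queries shorter than its k, so the single value 22 is used for both
(configurable). Seeds co-linear within one unitig merge greedily into long
match blocks before position expansion; a block placing at more than 1000
positions keeps a seeded-random 1000.

Blocks on the same anchor and strand are chained by sparse DP:

    f(p) = max( L(p), max_{q<p} f(q) + L(pq) − θ(p,q) ),
    θ(p,q) = 0.125·|(LSpR−LSqR) − (LSpr−LSqr)| + 3,

where `L(pq)` excludes the read overlap with the predecessor. The diagonal
difference is taken in absolute value — as a signed quantity the penalty
could be negative and would reward misordered seeds — and a transition is
refused when θ exceeds `L(pq)` (chain split). The top 12 chains are
extended: exact blocks are kept verbatim, inter-block gaps are closed with
global alignment, and read ends beyond the outer blocks extend
semi-globally, soft-clipping what does not pay. Scoring is BWA-MEM-like:
match +1, mismatch −4, gap open −6 for the first gapped base, −1 per
further base (configurable); the same scheme scores original alignments
(from the AS tag when present, else recomputed) so that new and old scores
are directly comparable.

## Pair rescoring and the improvement filter

The insert-size model is a robust fit (median and 1.4826·MAD of |ISIZE|)
over proper pairs of the input alignment, with a configurable fallback below
100 pairs, and a ±1 bp floor on the acceptance interval for degenerate
samples. A combination is *proper* when orientations are FR and the
projected span falls within mean ± 1.5 sd; for anchor/original mixtures the
original coordinate is tested in both of its donor interpretations (raw and
shifted by the SV length). The pair score maximizes
`s(R1_p) + s(R2_q) + K·[proper]` exhaustively over all candidates
(≤ 13 per end); K defaults to 50 — a third of a read's match score, large
enough to overturn small score differences but not a 60 bp clip.

A pair is kept only when its best combination *strictly* beats the best
all-original combination. Ties go to "unmapped": if realignment cannot
improve a pair, it carries no anchor evidence — this single rule discards
both error-only noise pairs (which tie) and pairs for which no anchor
candidate exists. Among equal best combinations the one using more
realigned ends wins, then the lowest anchor id (determinism).

## Clustering, assembly, inference

Known SVs group greedily along the genome: an SV joins a group when its
upstream breakpoint lies within 50 bp of the group's running downstream
border. Only the two SVs with the most supporting reads survive per group
(reads are counted after pair filtering); reads on dropped anchors
re-assign to whichever survivor shares more distinct k-mers with the read,
uniform-seeded on ties.

Before assembly, 64 bp blocks whose coverage exceeds 1.5× the genome-wide
mean lose their lowest-scoring reads (ties removed by read name), and a
cluster is discarded as uncertain when over 80 % of its reads had original
MAPQ 0 *and* the median realignment score gain is ≤ 5 (one mismatch's
worth) — the guard that suppresses mobile-element-like regions where reads
map everywhere equally badly.

Assembly is a greedy word-overlap consensus (word 25 bp, ≥ 3 reads per
contig, extension by majority vote with ≥ 2 supporting reads; a lone voter
may extend only while unanimous, which lets contig edges reach single-read
coverage without letting errors win votes elsewhere). SV regions longer
than 500 bp are assembled in 500 bp blocks. Each read records its join
position; reads realign to the contig mismatch-only (≤ 3 mismatches, else
excluded) to produce per-base consensus depth. All pool reads may support
any contig they share a word with, and per-position depth aggregates across
contigs by maximum — two contigs from one pool overlap at seams and share
reads, so summing member-only depth would artificially halve seam coverage.

Consensus contigs align globally (free end gaps both sides: contigs may
legitimately overhang the anchor) against candidate anchor windows derived
from their supporting reads' placements, deduplicated within 50 bp. A
contig is discarded when all candidates are out of range or when none of
its reads improved on its original alignment score. Mismatches and indels
versus the anchor are recorded in anchor coordinates, alongside projected
depth.

The anchor's own SV is called when consensus depth reaches `depth_min` at
both breakpoints. Because the panel breakpoint may sit up to ~10 bp from
the donor junction (where the alignment then places a short indel run with
zero depth), breakpoint depth is evaluated as the maximum within a 50 bp
window on each side. For insertions the interior must also be covered:
judged per 64 bp block *mean* at `max(3, depth_min/2)` rather than a
per-base minimum — at 30× a heterozygous allele yields only ~mean/3
consensus depth after extraction, and a per-base minimum at `0.2·mean`
would reject long het insertions on single-base sampling dips while an
absent allele still scores zero everywhere. `depth_min` defaults to
`max(3, 0.2·mean coverage)`.

The reported allele is reconstructed by applying *all* consensus-vs-anchor
variants inside the jitter-widened insert window to the anchor sequence:
this recovers the donor's allele (divergent positions corrected) and a
rotation-consistent placement at the panel position even when the panel
breakpoint is jittered; net indels adjust the SV length. Indel variants
≥ 50 bp found away from the junction window become additional calls at
their lifted genome positions. Calls shorter than 50 bp are dropped
(the inclusive reading of the community ≥ 50 bp convention).

Genotyping uses coverage fractions: alt support is the breakpoint consensus
depth; reference support counts original-alignment reads spanning the
breakpoint contiguously (full-match CIGAR across ±20 bp — an SV-carrying
read cannot do that). Fraction ≥ 0.8 → 1/1, ≥ 0.2 → 0/1, below → dropped
as noise; zero total depth → `./.`. Final positions are left-normalized
against the original reference (adjust first, then normalize).

## Synthetic worlds

The generator's defaults are the stated evaluation conditions: 200 kb
genome at GC 0.5, 20 non-overlapping SVs of 60–1000 bp (alternating
DEL/INS, alternating hom/het, ≥ 1 kb separation), 2×150 bp reads at 30×
total depth, insert 400 ± 50 (truncated at ±3 sd so proper-pair flags are
unambiguous), substitution errors at 0.2 % (typical Illumina scale; indel
errors off so the perfect-pair definition stays crisp), panel jitter
≤ 10 bp, allele divergence 2 % (substitutions only, so true SV lengths are
preserved and length recovery is a genuine test of inference, not of the
generator), leave-out fraction 0 (set to 1 for the negative control).
Everything is byte-deterministic under the seed.

The bundled "original aligner" projects each read through the known
donor→reference segment map: fully reference reads become full matches,
junction-spanning reads are soft-clipped at the breakpoint (< 20 bp anchor
→ unmapped), insert-interior reads are unmapped, and proper-pair flags
require full-length FR pairs within 4 sd. It reproduces the signature
*classes* a real aligner emits, not its errors: no mapping ambiguity, no
reference-bias mismatches, no chimeric split records with SA tags. A green
end-to-end test therefore establishes that the pipeline converts clean
SV signatures into correct, genotyped calls under panel divergence and
jitter — not that it tolerates aligner-specific artifacts of real BAMs.
Real-data concerns deliberately out of scope: ALU-scale genome-wide repeat
families (the MAPQ-0 filter is implemented but exercised only via unit
tests), multi-sample panels, and CRAM input.

## Known limitations

* Proper pairing across *different* anchors is not recognized; mates on two
  anchors score without the bonus.
* The greedy assembler can fragment a cluster into overlapping contigs;
  depth aggregation compensates, but a breakpoint falling exactly at a
  contig seam in a read-sampling cold spot can still lose its call (one
  such honest miss exists in the committed end-to-end world: a 102 bp het
  insertion with breakpoint-window depth 5 against a threshold of 6).
* Insertions much longer than the insert size rely on both-unmapped pairs;
  at low depth their interior blocks may fall below the coverage rule.
* Single-threaded by design; the stages parallelize over anchor groups in
  principle but no parallel path is implemented.
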