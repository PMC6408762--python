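# Methods

## Scope and model

`circas` operates on already-aligned short reads (50–150 bp, paired-end)
from a spliced aligner that reports chimeric alignments as primary +
supplementary records. It is aligner-agnostic: all evidence is taken from
one SAM/BAM — gapped CIGARs for internal splice junctions, supplementary
segments for back-splices. Coordinates are 1-based inclusive everywhere in
memory (the GTF/SAM convention); only BED export converts to 0-based
half-open, exactly once.

### Back-splice junctions

A back-splice candidate requires two aligned segments of one read on the
same chromosome and strand whose read offsets are contiguous within ±2
bases (tolerating aligner end-trimming) and whose genomic order is inverted
relative to their order in the read. Offsets are measured as the leading
clip in SAM stored orientation; under that convention "later in the stored
read maps strictly upstream" characterizes a back-splice on either strand,
so no strand-specific case split is needed. The circle start is the
leftmost base of the downstream-in-read segment, the end the rightmost base
of the upstream-in-read segment.

Candidates are grouped by exact coordinates — no fuzzy merge window — and
kept when (a) the intronic flanks read `GT..AG` or `CT..AC` (the canonical
splice motif observed on the genomic plus strand for plus- and minus-strand
transcription respectively) and (b) at least `min_bsj_support` distinct
reads support the group. The motif also fixes the transcription strand
(`GTAG` → `+`, `CTAC` → `-`); read flags are not trusted for strandedness
because library strandedness is generally unknown. `min_bsj_support`
defaults to 2: a single chimeric alignment is a common artifact class,
while two independent reads at identical coordinates with a canonical motif
rarely are.

### Read assignment and internal junctions

Each circle receives its BSJ-spanning reads plus every mate of such a read
whose aligned blocks (including supplementary segments) lie entirely within
the circle span. Reads satisfying several (nested) circles go to each.
Within assigned reads, a reference gap of at least `min_intron_len` (30 bp)
between consecutive aligned blocks defines a junction; smaller gaps are
treated as deletions and absorbed. 30 bp is below essentially all annotated
human introns and above common indel artifacts. Junctions are aggregated by
exact coordinates with distinct-read support and must pass the same
canonical-motif filter.

Supplementary segments carry their full block structure, not just a span:
a chimeric segment that itself crosses an internal junction must contribute
that junction, and must *not* present a single contiguous span that would
fake retained-intron coverage.

### Exon correction

A junction is kept only if its donor equals an annotated exon end or its
acceptor equals an annotated exon start (either side suffices). This
suppresses junctions from misalignments at the cost of fully novel exons;
`--no-correct` retains uncorrected junctions, flagged, for novel-exon
exploration.

### Event classification

Within one circle, with `J` the corrected junction set:

* **A5SS / A3SS** — two junctions sharing one boundary. A pair sharing the
  acceptor and differing in donor (d1 < d2) yields the alternative segment
  `(d1+1, d2)`; sharing the donor with acceptors a1 < a2 yields
  `(a1, a2−1)`. The name follows the transcribed strand (fixed by the BSJ
  motif): a shared-acceptor pair is A5SS on `+` and A3SS on `-`, and vice
  versa. Inclusion support is the junction of the isoform *containing* the
  alternative segment; exclusion the other.
* **SE** — a junction `(d, a)` together with an annotated exon `(s, e)`
  satisfying `d < s ≤ e < a`, plus inclusion evidence: distinct reads with
  a junction into `s` or out of `e`, or failing that, reads whose block
  overlaps the exon by at least `min_overlap` (8 bp). The stricter
  junction-anchored evidence is preferred; the coverage fallback only
  engages when no inclusion junction was observed.
* **RI** — a junction `(d, a)` coinciding with an annotated intron, plus at
  least one read whose single block covers `(d, a+1)` contiguously, i.e.
  spans the intron unspliced. The alternative segment is the intron
  `(d+1, a−1)`; inclusion support is the count of spanning reads.

**Exon-skipping suppression.** Taken literally, the pair rules double-call
every SE locus: the skip junction shares its donor with the inclusion
junction into the skipped exon (an apparent A3SS) and its acceptor with the
junction out of it (an apparent A5SS). A pair is therefore suppressed when
an annotated exon lies strictly inside the pair's differing region with its
matching boundary on the varied side — i.e. for donors d1 < d2 sharing an
acceptor, some exon ends at d2 and starts after d1; symmetrically for
acceptors. Genuine A5SS/A3SS events are unaffected: their varied boundary
either is not an annotated exon edge, or belongs to an exon extending
outside the pair gap. The corresponding limitation: a real A3SS whose
proximal acceptor coincides with a short annotated exon ending inside the
pair gap would be classified through the SE route instead.

Every event must satisfy containment (`circ.start ≤ alt_start ≤ alt_end ≤
circ.end`) and the dual-isoform rule (`incl_reads ≥ 1` and
`excl_reads ≥ 1`): alternative splicing is only called when both forms are
observed. Events are deduplicated by (circle, type, segment) and are
circle-scoped: the same genomic segment inside two distinct circles gives
two events. The host gene is the transcript whose boundaries anchored the
event, ties broken mRNA > lncRNA > other (a coding-gene overlap dominates),
then lexicographically for determinism.

## Comparison and characterization

Events are keyed by `(chrom, circ_start, circ_end, type, alt_start,
alt_end)`. Cross-condition classes are assigned by presence/absence only —
no expression-level test — partitioning keys into A-specific, B-specific
and common; a `--merge-window N` option (default 0, exact matching) chains
keys whose coordinates all agree within N bp.

Per-type flanking-intron length:

* A5SS/A3SS: the intron remaining between the distal variant boundary and
  the shared boundary (`shared − alt_end − 1` for shared-acceptor pairs,
  `alt_start − shared − 1` for shared-donor pairs);
* SE: the mean of the skipped exon's two flanking intron lengths in the
  host transcript (null when no host transcript is known);
* RI: the retained intron's own length.

Summary tables report per-class type counts and percentages (full precision
internally, one decimal for display), per-class per-type mean intron length
with the standard error of the mean (sample SD/√n), and the mRNA/lncRNA
host split (hosts of biotype "other" are counted separately and excluded
from the two-way percentage). The gene-list occurrence table counts events
of a chosen class per (gene, type) against a user list, matching symbols
case-insensitively; pathway/GO enrichment is deliberately out of scope.

The events TSV carries the fixed column contract (sample, circle, strand,
type, segment, support, host, corrected). The shared-boundary coordinate of
A5SS/A3SS pairs is not serialized, so a comparison run from TSVs alone can
compute intron lengths only for RI; the library path, holding live event
objects and the annotation, computes all four types.

## Synthetic data generator

The simulator emulates an RNase-R-enriched circRNA library at desk scale.
Defaults (chosen once as the study conditions): 3 contigs × 200 kb; 20
circle-hosting genes of 5–8 exons (~80% protein-coding, 20% lincRNA, on
random strands) plus 5 linear background genes; one planted event per
circle, 5 of each type; two isoforms per circle at 0.5/0.5 abundance; 30×
circle coverage with 2×100 bp pairs, fragment length 300 ± 40 bp; 200
linear background read pairs.

Circles are compact 3-exon subsets of their gene (4 exons for SE), exon
lengths 90–140 bp: fragments rolled around the circle must be able to place
one mate over any internal junction while the other crosses the BSJ,
otherwise the junction is undetectable by construction rather than by
method failure. Retained introns are planted 40–60 bp long at the first
circle junction for the same reason — a single 100 bp read must span the
intron contiguously, which also mirrors why RI is the rarest event class in
real catalogs. Fragment starts are uniform on the circle circumference;
`bsj_read_fraction` (0.2) enforces a floor of BSJ-crossing pairs by
stratified sampling, alternating which mate carries the chimeric junction
so assigned mates fall on both sides of the back-splice.

Canonical motifs are written into the genome at every junction flank
(GT/AG or CT/AC by gene strand, including the alternative A5SS/A3SS
boundaries and the BSJ flanks). Decoys are planted on SE circles: a
junction with deliberately non-canonical flanks sharing an acceptor with a
real junction (exercises the motif filter), and a canonical-motif junction
pair with both boundaries away from any annotated exon edge (exercises exon
correction: visible only under `--no-correct`). All alignments are emitted
on the forward strand with correct pairing flags; the reader's
stored-orientation offset convention is exercised separately with
hand-built reverse-strand records in the unit tests.

What the generator does *not* emulate: sequencing errors and quality
variation, PCR duplicates, multi-mapping ambiguity, expression gradients
across isoforms, trans-chromosomal chimeras, or more than two isoforms per
circle. Passing the recovery tests therefore demonstrates correctness of
the detection logic under clean evidence, not robustness to alignment
noise.

Two worked-example fixtures rebuild experimentally studied events at their
real coordinates — circUBAP2L (chr1:154,234,591–154,235,291, +) with two
isoforms whose 5' splice sites differ by 33 bp, and circRAB6A
(chr11:73,707,420–73,718,718, −) with a skipped 95 bp exon. Their contigs
are synthetic: N bases pad up to a window around the circle so the printed
genomic coordinates hold literally; only the window carries real (seeded
random) sequence with planted motifs.

## Numerical and degenerate-input choices

* All aggregation is by exact integer coordinates; no floating point enters
  detection. Outputs are sorted (chrom, circle, segment, type), making
  reruns byte-identical.
* Distinct-read support counts (read name, mate) pairs, so one fragment's
  two mates each count once, and a junction observed in both the primary
  and supplementary part of the same read counts once.
* Empty inputs are valid: an empty alignment file yields an empty
  (header-only) events table and exit 0; an empty comparison class yields
  all-zero rows without division errors (percentages of an empty class are
  0, intron-length SE is NaN for n < 2).
* Junctions within 2 bp of a chromosome edge fail the motif check with a
  logged warning rather than raising.
* Scale: the full default simulation plus detection runs in a few seconds
  on one CPU; the worked examples are dominated by building the N-padded
  contigs (~150 MB strings) and stay under ten seconds each.

## Known limitations

* Novel (unannotated) exons are invisible under default correction.
* Condition comparison is presence/absence; differential usage of a common
  event is not tested.
* A5SS/A3SS calls need both isoform junctions in the same sample's assigned
  reads; events supported only across samples are not merged.
* Exact-coordinate matching across samples assumes a shared reference and
  aligner; `--merge-window` is the escape hatch, not the default.
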