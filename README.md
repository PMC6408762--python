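# circas

Alternative splicing **inside** circular RNAs (circ-AS), from short-read
RNA-seq alignments.

Circular RNAs (circRNAs) arise by back-splicing: a downstream splice donor
joins an upstream splice acceptor, closing the transcript into a covalent
circle. Beyond that diagnostic back-splice junction (BSJ), a circRNA's
*internal* structure can itself be alternatively spliced, producing distinct
circle isoforms — a layer of variation that standard linear-AS tools never
see. `circas` detects it, and compares it between conditions (e.g. tumor vs
adjacent normal tissue in RNase-R-enriched libraries), for whoever needs a
catalog of condition-specific circRNA isoform events: SE (skipped exon), RI
(retained intron), A5SS and A3SS (alternative 5'/3' splice sites).

## Method

Per sample, from a spliced/chimeric SAM/BAM, a genome FASTA and an exon GTF:

1. **Back-splice detection.** A read whose aligned segments appear in
   *inverted* genomic order (the later part of the read maps upstream of the
   earlier part, with contiguous read offsets) spans a BSJ. Candidates are
   grouped by exact coordinates; a circle `chrom:start-end` is kept when the
   flanking dinucleotides read `GT..AG` (plus-strand transcription) or
   `CT..AC` (minus), and at least `min_bsj_support` (default 2) distinct
   reads support it.
2. **Read assignment.** Each circle collects its BSJ-spanning reads plus
   every mate falling entirely within the circle span.
3. **Internal junctions.** Reference gaps ≥ 30 bp in assigned reads define
   (donor, acceptor) junctions; non-canonical junctions are dropped, and a
   junction must have at least one boundary identical to an annotated exon
   boundary (exon correction; `--no-correct` disables this).
4. **Event classification.** Two junctions sharing an acceptor but differing
   in donor → A5SS (A3SS on the minus strand); sharing a donor → A3SS/A5SS.
   A junction skipping over an annotated exon, with independent inclusion
   evidence, → SE. A junction coinciding with an annotated intron that other
   reads cover contiguously → RI. Every event carries read support for
   *both* isoforms.
5. **Comparison.** Event catalogs of two conditions are partitioned into
   A-specific / B-specific / common by presence/absence of the exact event
   key, with summary statistics (type ratios, mean flanking-intron length ±
   SE, mRNA/lncRNA host split, gene-list occurrence tables).

A deterministic simulator (`circas simulate`, `circas.simulate`) generates
mini-genomes with planted circles, isoforms, canonical motifs, decoy
junctions and rolling-circle paired-end reads, together with the truth
tables the test suite scores against.

## Worked example

```bash
circas simulate --out demo/sim --seed 1 --n-circles 4 --coverage 30
circas detect --bam demo/sim/reads.sam --ref demo/sim/ref.fa \
              --gtf demo/sim/annotation.gtf --out demo/det --sample tumor1
cat demo/det/events.tsv
```

```
sample  circ_chrom  circ_start  circ_end  circ_strand  event_type  alt_start  alt_end  alt_len  incl_reads  excl_reads  host_gene  host_biotype  corrected
tumor1  ctg1        3773        5179      -            SE          4589       4685     97       13          3           GENE1      mRNA          1
tumor1  ctg1        10131       11002     +            A3SS        10891      10940    50       7           14          GENE4      mRNA          1
tumor1  ctg2        4457        4983      -            RI          4553       4606     54       2           4           GENE2      mRNA          1
tumor1  ctg3        4503        5370      +            A5SS        5033       5081     49       6           8           GENE3      mRNA          1
```

Each row is one event inside one detected circle: the circle span and
motif-derived strand, the event type, the alternative segment (the skipped
exon for SE, the retained intron for RI, the extension segment for
A5SS/A3SS) with its length, distinct-read support for the inclusion and
exclusion isoforms, and the host gene/biotype assigned through the
annotation boundaries that corrected the junctions. All four planted events
are recovered exactly. `circs.bed` holds the circle spans (BED6, score =
BSJ read support), and `run_manifest.json` records parameters and input
checksums for reproducibility.

Condition comparison:

```bash
circas compare --group-a tumorA.tsv,tumorB.tsv --group-b normalA.tsv,normalB.tsv \
               --label-a tumor --label-b normal --out cmp --gene-list oncogenes.txt
```

writes `comparison.tsv` (one row per event key: per-condition sample counts
and its class), `summary.txt` (type ratios, intron lengths, biotype split
per class) and a per-gene occurrence table for the supplied gene list.

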