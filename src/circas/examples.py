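"""Reconstructed worked-example circRNA fixtures.

Two experimentally studied circRNA splicing events are rebuilt as synthetic
fixtures at their real genomic coordinates:

* circUBAP2L (chr1:154,234,591-154,235,291, plus strand): an A5SS event in
  which a 33 bp portion of a partial exon is alternatively spliced, giving
  two circle isoforms.
* circRAB6A (chr11:73,707,420-73,718,718, minus strand): an SE event
  skipping a 95 bp internal exon.

The contigs are synthetic: N bases pad up to a window around each circle so
that the printed genomic coordinates hold literally, real (seeded random)
sequence fills the window, and canonical splice motifs are written at every
junction flank.  Reads are sampled by the same rolling-circle simulator used
for the random fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ExonModel, GenomeRef
from .simulate import SimParams, TruthCircle, _sam_text, reads_for_circle


@dataclass
class ExampleFixture:
    genome: GenomeRef
    models: list[ExonModel]
    circle: TruthCircle
    sam_text: str
    expected_type: str
    expected_alt: tuple[int, int]
    n_read_pairs: int


def _make_contig(
    rng: np.random.Generator,
    length: int,
    window: tuple[int, int],
    plants: list[tuple[int, bytes]],
) -> str:
    buf = np.full(length, ord("N"), dtype=np.uint8)
    ws, we = window
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    buf[ws - 1 : we] = bases[rng.integers(0, 4, we - ws + 1)]
    for pos, motif in plants:
        buf[pos - 1 : pos - 1 + len(motif)] = np.frombuffer(motif, dtype=np.uint8)
    return buf.tobytes().decode("ascii")


def _simulate(fixture_rng, genome, circle, params) -> tuple[str, int]:
    records: list[dict] = []
    n = reads_for_circle(fixture_rng, genome, circle, params, records, prefix="ex")
    return _sam_text(genome, records), n


def a5ss_example(seed: int = 1, params: SimParams | None = None) -> ExampleFixture:
    """Two-isoform circUBAP2L fixture with a 33 bp alternative 5' splice site."""
    params = params or SimParams(seed=seed)
    rng = np.random.default_rng(params.seed)
    chrom = "chr1"
    S, E = 154234591, 154235291
    exon_a = (S, S + 149)
    exon_b = (S + 300, S + 479)          # proximal 5' splice site
    exon_b_long = (S + 300, S + 512)     # distal site: 33 bp further
    exon_c = (S + 560, E)
    plants = [
        (S + 150, b"GT"), (S + 298, b"AG"),       # intron between A and B
        (S + 480, b"GT"),                          # donor after short B
        (S + 513, b"GT"),                          # donor after long B
        (S + 558, b"AG"),                          # shared acceptor into C
        (E + 1, b"GT"), (S - 2, b"AG"),            # back-splice flanks
    ]
    genome = GenomeRef(
        {chrom: _make_contig(rng, E + 300, (S - 150, E + 250), plants)}
    )
    circle = TruthCircle(
        chrom=chrom,
        start=S,
        end=E,
        strand="+",
        gene_name="UBAP2L",
        isoforms=((exon_a, exon_b, exon_c), (exon_a, exon_b_long, exon_c)),
        weights=(0.5, 0.5),
        planted_events=(("A5SS", S + 480, S + 512),),
    )
    models = [
        ExonModel(
            transcript_id="UBAP2L-201",
            gene_id="UBAP2L",
            gene_name="UBAP2L",
            chrom=chrom,
            strand="+",
            exons=(exon_a, exon_b, exon_c),
            biotype="mRNA",
        )
    ]
    sam_text, n = _simulate(rng, genome, circle, params)
    return ExampleFixture(
        genome=genome,
        models=models,
        circle=circle,
        sam_text=sam_text,
        expected_type="A5SS",
        expected_alt=(S + 480, S + 512),
        n_read_pairs=n,
    )


def se_example(seed: int = 1, params: SimParams | None = None) -> ExampleFixture:
    """Two-isoform circRAB6A fixture with a skipped 95 bp internal exon."""
    params = params or SimParams(seed=seed)
    rng = np.random.default_rng(params.seed)
    chrom = "chr11"
    S, E = 73707420, 73718718
    exon_a = (S, S + 199)
    exon_b = (S + 3000, S + 3094)        # the 95 bp skipped exon
    exon_c = (S + 7000, S + 7199)
    exon_d = (E - 249, E)
    plants = [
        (S + 200, b"CT"), (S + 2998, b"AC"),       # intron A..B
        (S + 3095, b"CT"), (S + 6998, b"AC"),      # intron B..C
        (S + 7200, b"CT"), (E - 252, b"AC"),       # intron C..D
        (E + 1, b"CT"), (S - 2, b"AC"),            # back-splice flanks
    ]
    genome = GenomeRef(
        {chrom: _make_contig(rng, E + 300, (S - 150, E + 250), plants)}
    )
    circle = TruthCircle(
        chrom=chrom,
        start=S,
        end=E,
        strand="-",
        gene_name="RAB6A",
        isoforms=((exon_a, exon_b, exon_c, exon_d), (exon_a, exon_c, exon_d)),
        weights=(0.5, 0.5),
        planted_events=(("SE", S + 3000, S + 3094),),
    )
    models = [
        ExonModel(
            transcript_id="RAB6A-201",
            gene_id="RAB6A",
            gene_name="RAB6A",
            chrom=chrom,
            strand="-",
            exons=(exon_a, exon_b, exon_c, exon_d),
            biotype="mRNA",
        )
    ]
    sam_text, n = _simulate(rng, genome, circle, params)
    return ExampleFixture(
        genome=genome,
        models=models,
        circle=circle,
        sam_text=sam_text,
        expected_type="SE",
        expected_alt=(S + 3000, S + 3094),
        n_read_pairs=n,
    )
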