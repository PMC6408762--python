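"""Deterministic synthetic data: mini-genome, annotation, reads, truth tables.

The generator emulates an RNase-R-enriched circRNA sequencing library: each
planted circRNA has two isoforms differing by exactly one splicing event
(SE, RI, A5SS or A3SS), canonical splice motifs written into the genome at
every junction flank, paired-end reads sampled by rolling the circle (so a
fraction of reads crosses the back-splice junction and is emitted as a
chimeric primary + supplementary record pair), spliced reads with skip-gapped
CIGARs over internal junctions, and linear background reads from non-circle
genes.  Decoy junctions (non-canonical motifs, annotation-unmatched
boundaries) are planted for negative controls.

All output is reproducible byte-for-byte from the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .io import ExonModel, GenomeRef, write_fasta, write_gtf

log = logging.getLogger("circas")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_EVENT_CYCLE = ("SE", "RI", "A5SS", "A3SS")


@dataclass
class SimParams:
    """Study conditions of the simulation.

    Read lengths and the paired-end layout mirror short-read RNA-seq
    (50-150 bp); the default scale (3 contigs x 200 kb, 20 circles at 30x)
    keeps a full pipeline run on one CPU well under a minute.
    """

    seed: int = 1
    read_len: int = 100
    fragment_mean: int = 300
    fragment_sd: int = 40
    coverage: float = 30.0
    bsj_read_fraction: float = 0.2
    background_linear_reads: int = 200
    n_circles: int = 20
    n_events_per_type: Optional[int] = None
    n_contigs: int = 3
    contig_len: int = 200_000
    n_background_genes: int = 5
    decoys: bool = True

    def __post_init__(self) -> None:
        if self.read_len < 50:
            raise ValueError("read_len must be >= 50")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.n_events_per_type is not None:
            self.n_circles = 4 * self.n_events_per_type


@dataclass(frozen=True)
class TruthCircle:
    """One planted circRNA: two isoform exon-chains and the implied event."""

    chrom: str
    start: int
    end: int
    strand: str
    gene_name: str
    isoforms: tuple[tuple[tuple[int, int], ...], ...]
    weights: tuple[float, ...]
    planted_events: tuple[tuple[str, int, int], ...]


@dataclass(frozen=True)
class DecoySpec:
    """A planted junction that must never give rise to an event."""

    chrom: str
    donor: int
    acceptor: int
    kind: str  # "noncanonical" | "uncorrected"
    wb_alt_start: int  # the alt segment a failure of the filter would report
    wb_alt_end: int
    circle_start: int
    circle_end: int


@dataclass
class SimBundle:
    genome: GenomeRef
    models: list[ExonModel]
    circles: list[TruthCircle]
    decoys: list[DecoySpec]
    sam_text: str
    truth_bsj: pd.DataFrame
    truth_events: pd.DataFrame
    n_read_pairs: int


# ---------------------------------------------------------------------------
# genome + annotation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> bytearray:
    return bytearray(_BASES[rng.integers(0, 4, n)].tobytes())


def _plant(buf: bytearray, pos: int, bases: bytes) -> None:
    buf[pos - 1 : pos - 1 + len(bases)] = bases


@dataclass
class _Gene:
    gid: int
    chrom: str
    strand: str
    biotype: str
    exons: list[tuple[int, int]]
    event: Optional[str]  # named event type or None for background genes
    c0: int = 1  # first exon of the circle (absolute index)
    span: int = 3  # number of exons in the circle
    isoforms: tuple = ()
    truth_event: Optional[tuple] = None
    decoys: list[DecoySpec] = field(default_factory=list)
    plants: list[tuple[int, bytes]] = field(default_factory=list)

    @property
    def circle(self) -> tuple[int, int]:
        return (self.exons[self.c0][0], self.exons[self.c0 + self.span - 1][1])


def _donor_motif(strand: str) -> bytes:
    return b"GT" if strand == "+" else b"CT"


def _acceptor_motif(strand: str) -> bytes:
    return b"AG" if strand == "+" else b"AC"


def _build_gene(
    rng: np.random.Generator,
    gid: int,
    chrom: str,
    left: int,
    strand: str,
    biotype: str,
    event: Optional[str],
    with_decoys: bool,
) -> _Gene:
    n_ex = int(rng.integers(5, 9))
    # circles are compact exon subsets: paired-end fragments rolled around
    # the circle must be able to reach every internal junction
    span = 4 if event == "SE" else 3
    if event == "SE":
        n_ex = max(n_ex, 6)
    c0 = int(rng.integers(1, n_ex - span))
    ex_lens = [int(x) for x in rng.integers(90, 221, n_ex)]
    for k in range(c0, c0 + span):
        ex_lens[k] = int(rng.integers(90, 122))
    in_lens = [int(x) for x in rng.integers(150, 601, n_ex - 1)]

    skip_abs = ri_intron = var_intron = delta = None
    right_var = False
    if event == "SE":
        skip_abs = c0 + 2
        if with_decoys:
            ex_lens[c0] = 150
            ex_lens[c0 + 1] = max(ex_lens[c0 + 1], 100)
    elif event == "RI":
        # retained-intron evidence needs an assigned read whose single block
        # spans the whole intron: keep the intron well under the read length
        # and at the first circle junction, where paired-end fragments
        # anchored at the back-splice can reach it
        ri_intron = c0
        for k in range(c0, c0 + span):
            ex_lens[k] = int(rng.integers(90, 112))
        in_lens[ri_intron] = int(rng.integers(40, 61))
    elif event in ("A5SS", "A3SS"):
        var_intron = c0 + int(rng.integers(0, span - 1))
        delta = int(rng.integers(20, 61))
        right_var = (event == "A5SS") == (strand == "+")
        if right_var:
            in_lens[var_intron] = delta + int(rng.integers(60, 200))
        else:
            ex_lens[var_intron + 1] = max(ex_lens[var_intron + 1], delta + 60)

    exons: list[tuple[int, int]] = []
    pos = left
    for k in range(n_ex):
        s, e = pos, pos + ex_lens[k] - 1
        exons.append((s, e))
        pos = e + 1 + (in_lens[k] if k < n_ex - 1 else 0)

    gene = _Gene(
        gid=gid, chrom=chrom, strand=strand, biotype=biotype, exons=exons,
        event=event, c0=c0, span=span,
    )

    for k in range(n_ex - 1):
        istart, iend = exons[k][1] + 1, exons[k + 1][0] - 1
        gene.plants.append((istart, _donor_motif(strand)))
        gene.plants.append((iend - 1, _acceptor_motif(strand)))

    if event is None:
        return gene

    base = tuple(exons[c0 : c0 + span])
    if event == "SE":
        s_k, e_k = exons[skip_abs]
        iso_b = tuple(x for x in base if x != (s_k, e_k))
        gene.isoforms = (base, iso_b)
        gene.truth_event = ("SE", s_k, e_k)
        if with_decoys:
            c0s, c0e = exons[c0]
            c1s, _ = exons[c0 + 1]
            d_nc = c0e - 7
            gene.plants.append((d_nc + 1, b"AA"))
            gene.decoys.append(
                DecoySpec(chrom, d_nc, c1s, "noncanonical", d_nc + 1, c0e, *gene.circle)
            )
            d2, d3, a2 = c0e - 60, c0e - 45, c1s + 50
            gene.plants.append((d2 + 1, _donor_motif(strand)))
            gene.plants.append((d3 + 1, _donor_motif(strand)))
            gene.plants.append((a2 - 2, _acceptor_motif(strand)))
            gene.decoys.append(
                DecoySpec(chrom, d2, a2, "uncorrected", d2 + 1, d3, *gene.circle)
            )
            gene.decoys.append(
                DecoySpec(chrom, d3, a2, "uncorrected", d2 + 1, d3, *gene.circle)
            )
    elif event == "RI":
        i = ri_intron
        e_i, s_n = exons[i][1], exons[i + 1][0]
        ci = i - c0  # chain index of the upstream exon within the circle
        iso_b = base[:ci] + ((exons[i][0], exons[i + 1][1]),) + base[ci + 2 :]
        gene.isoforms = (base, iso_b)
        gene.truth_event = ("RI", e_i + 1, s_n - 1)
    else:
        i = var_intron
        e_i, s_n = exons[i][1], exons[i + 1][0]
        if right_var:
            e2 = e_i + delta
            gene.plants.append((e2 + 1, _donor_motif(strand)))
            ci = i - c0
            iso_b = base[:ci] + ((exons[i][0], e2),) + base[ci + 1 :]
            gene.truth_event = (event, e_i + 1, e2)
        else:
            a2 = s_n + delta
            gene.plants.append((a2 - 2, _acceptor_motif(strand)))
            ci = i - c0 + 1
            iso_b = base[:ci] + ((a2, exons[i + 1][1]),) + base[ci + 1 :]
            gene.truth_event = (event, s_n, a2 - 1)
        gene.isoforms = (base, iso_b)
    return gene


def make_genome_and_annotation(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> tuple[GenomeRef, list[ExonModel], list[TruthCircle], list[DecoySpec]]:
    """Seeded genome, transcript annotation, circle truth and decoy table."""
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    contigs = [f"ctg{i + 1}" for i in range(params.n_contigs)]
    buffers = {c: _random_seq(rng, params.contig_len) for c in contigs}
    cursors = {c: 1000 for c in contigs}

    schedule: list[Optional[str]] = [
        _EVENT_CYCLE[i % 4] for i in range(params.n_circles)
    ] + [None] * params.n_background_genes

    genes: list[_Gene] = []
    for gid, event in enumerate(schedule, 1):
        chrom = contigs[(gid - 1) % len(contigs)]
        left = cursors[chrom] + int(rng.integers(1500, 4000))
        strand = "+" if rng.random() < 0.5 else "-"
        biotype = "mRNA" if rng.random() < 0.8 else "lncRNA"
        gene = _build_gene(
            rng, gid, chrom, left, strand, biotype, event,
            with_decoys=params.decoys and event == "SE",
        )
        if gene.exons[-1][1] > params.contig_len - 1000:
            raise ValueError(
                f"infeasible geometry: gene {gid} overflows contig {chrom} "
                f"({gene.exons[-1][1]} > {params.contig_len - 1000})"
            )
        cursors[chrom] = gene.exons[-1][1]
        genes.append(gene)

    for gene in genes:
        buf = buffers[gene.chrom]
        for pos, bases in gene.plants:
            _plant(buf, pos, bases)

    genome = GenomeRef({c: buffers[c].decode() for c in contigs})
    models = [
        ExonModel(
            transcript_id=f"TX{g.gid}",
            gene_id=f"G{g.gid}",
            gene_name=f"GENE{g.gid}",
            chrom=g.chrom,
            strand=g.strand,
            exons=tuple(g.exons),
            biotype=g.biotype,
        )
        for g in genes
    ]
    circles = []
    decoys = []
    for g in genes:
        if g.event is None:
            continue
        start, end = g.circle
        circles.append(
            TruthCircle(
                chrom=g.chrom,
                start=start,
                end=end,
                strand=g.strand,
                gene_name=f"GENE{g.gid}",
                isoforms=g.isoforms,
                weights=(0.5, 0.5),
                planted_events=(g.truth_event,),
            )
        )
        decoys.extend(g.decoys)
    # background models are the genes without an event; keep them in `models`
    return genome, models, circles, decoys


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _chain_len(chain: Sequence[tuple[int, int]]) -> int:
    return sum(e - s + 1 for s, e in chain)


def _map_window(
    chain: Sequence[tuple[int, int]], C: int, offset: int, length: int
) -> list[list[tuple[int, int]]]:
    """Genomic blocks of a transcript-coordinate window, split at the wrap.

    The circle axis is the concatenation of the chain blocks in ascending
    genomic order; crossing position C (the back-splice) starts a new part.
    """
    cum = []
    acc = 0
    for s, e in chain:
        cum.append(acc)
        acc += e - s + 1
    parts: list[list[tuple[int, int]]] = []
    cur: list[tuple[int, int]] = []
    p = offset % C
    remaining = length
    while remaining > 0:
        if p == 0 and cur:
            parts.append(cur)
            cur = []
        # locate block containing p
        idx = 0
        for i in range(len(chain) - 1, -1, -1):
            if cum[i] <= p:
                idx = i
                break
        off = p - cum[idx]
        blk_len = chain[idx][1] - chain[idx][0] + 1
        take = min(blk_len - off, remaining)
        gstart = chain[idx][0] + off
        cur.append((gstart, gstart + take - 1))
        p = (p + take) % C
        remaining -= take
    if cur:
        parts.append(cur)
    return parts


def _part_cigar(part: Sequence[tuple[int, int]], pre: int, post: int) -> str:
    ops = []
    if pre:
        ops.append(f"{pre}S")
    for i, (s, e) in enumerate(part):
        if i:
            gap = s - part[i - 1][1] - 1
            ops.append(f"{gap}N")
        ops.append(f"{e - s + 1}M")
    if post:
        ops.append(f"{post}S")
    return "".join(ops)


def _read_records(
    qname: str,
    mate_flag: int,
    chrom: str,
    chain: Sequence[tuple[int, int]],
    C: int,
    offset: int,
    read_len: int,
    genome: GenomeRef,
) -> list[dict]:
    """SAM records (primary first) for one read window on the circle axis."""
    parts = _map_window(chain, C, offset, read_len)
    seq = "".join(genome.fetch(chrom, s, e) for part in parts for s, e in part)
    lens = [sum(e - s + 1 for s, e in part) for part in parts]
    primary_idx = max(range(len(parts)), key=lambda i: lens[i])
    recs = []
    pre = 0
    for i, part in enumerate(parts):
        flag = 1 | mate_flag | (0 if i == primary_idx else 2048)
        recs.append(
            {
                "qname": qname,
                "flag": flag,
                "rname": chrom,
                "pos": part[0][0],
                "cigar": _part_cigar(part, pre, read_len - pre - lens[i]),
                "seq": seq,
            }
        )
        pre += lens[i]
    recs.sort(key=lambda r: 0 if not r["flag"] & 2048 else 1)
    return recs


def _emit_pair(
    records: list[dict],
    qname: str,
    chrom: str,
    chain: Sequence[tuple[int, int]],
    C: int,
    t: int,
    flen: int,
    read_len: int,
    genome: GenomeRef,
) -> None:
    r1 = _read_records(qname, 0x40, chrom, chain, C, t, read_len, genome)
    r2 = _read_records(qname, 0x80, chrom, chain, C, (t + flen - read_len) % C, read_len, genome)
    for rec in r1:
        rec["rnext"], rec["pnext"] = "=", r2[0]["pos"]
    for rec in r2:
        rec["rnext"], rec["pnext"] = "=", r1[0]["pos"]
    records.extend(r1)
    records.extend(r2)


def reads_for_circle(
    rng: np.random.Generator,
    genome: GenomeRef,
    circle: TruthCircle,
    params: SimParams,
    records: list[dict],
    prefix: str,
) -> int:
    """Rolling-circle paired-end sampling of one circle; returns pairs emitted."""
    rl = params.read_len
    n_pairs = 0
    for iso_idx, chain in enumerate(circle.isoforms):
        C = _chain_len(chain)
        total = params.coverage * C / (2 * rl)
        n_frags = max(8, int(round(total * circle.weights[iso_idx])))
        n_forced = math.ceil(params.bsj_read_fraction * n_frags)
        for f in range(n_frags):
            flen = int(np.clip(rng.normal(params.fragment_mean, params.fragment_sd), rl + 20, C))
            if f < n_forced:
                # stratified floor of BSJ-crossing pairs; alternate which
                # mate carries the chimeric junction so that assigned mates
                # fall on both sides of the back-splice
                w = int(rng.integers(10, rl - 9))
                t = (C - rl + w) if f % 2 == 0 else (C + w - flen) % C
            else:
                t = int(rng.integers(0, C))
            qname = f"{prefix}i{iso_idx}f{f:05d}"
            _emit_pair(records, qname, circle.chrom, chain, C, t, flen, rl, genome)
            n_pairs += 1
    return n_pairs


def _decoy_reads(
    genome: GenomeRef,
    circle: TruthCircle,
    decoy: DecoySpec,
    params: SimParams,
    records: list[dict],
    prefix: str,
    n_reads: int = 3,
) -> int:
    """Read pairs whose mate carries the decoy junction gap.

    Read 1 is a genuine BSJ-crossing read of the host circle (so the mate is
    assigned to the circle); read 2 is a gapped alignment over the decoy
    (donor, acceptor) junction, fully inside the circle span.
    """
    rl = params.read_len
    chain = circle.isoforms[0]
    C = _chain_len(chain)
    anchor = min(45, decoy.donor - decoy.circle_start, decoy.circle_end - decoy.acceptor)
    l1 = anchor + 1
    l2 = anchor
    blocks = [(decoy.donor - anchor, decoy.donor), (decoy.acceptor, decoy.acceptor + anchor - 1)]
    gap = decoy.acceptor - decoy.donor - 1
    seq2 = "".join(genome.fetch(circle.chrom, s, e) for s, e in blocks)
    for f in range(n_reads):
        qname = f"{prefix}d{decoy.kind[:2]}{decoy.donor}f{f}"
        r1 = _read_records(qname, 0x40, circle.chrom, chain, C, C - rl + 25, rl, genome)
        r2 = [
            {
                "qname": qname,
                "flag": 1 | 0x80,
                "rname": circle.chrom,
                "pos": blocks[0][0],
                "cigar": f"{l1}M{gap}N{l2}M",
                "seq": seq2,
                "rnext": "=",
                "pnext": r1[0]["pos"],
            }
        ]
        for rec in r1:
            rec["rnext"], rec["pnext"] = "=", r2[0]["pos"]
        records.extend(r1)
        records.extend(r2)
    return n_reads


def _background_reads(
    rng: np.random.Generator,
    genome: GenomeRef,
    bg_models: Sequence[ExonModel],
    params: SimParams,
    records: list[dict],
) -> int:
    """Spliced linear-transcript read pairs (no back-splice)."""
    if not bg_models or params.background_linear_reads <= 0:
        return 0
    rl = params.read_len
    n = 0
    while n < params.background_linear_reads:
        m = bg_models[int(rng.integers(0, len(bg_models)))]
        chain = m.exons
        L = _chain_len(chain)
        flen = int(np.clip(rng.normal(params.fragment_mean, params.fragment_sd), rl + 20, L))
        t = int(rng.integers(0, max(1, L - flen + 1)))
        qname = f"bg{n:06d}"
        _emit_pair(records, qname, m.chrom, chain, L, t, flen, rl, genome)
        n += 1
    return n


def _sam_text(genome: GenomeRef, records: Sequence[dict]) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name in genome.sequences:
        lines.append(f"@SQ\tSN:{name}\tLN:{genome.length(name)}")
    for r in records:
        lines.append(
            "\t".join(
                [
                    r["qname"],
                    str(r["flag"]),
                    r["rname"],
                    str(r["pos"]),
                    "60",
                    r["cigar"],
                    r.get("rnext", "*"),
                    str(r.get("pnext", 0)),
                    "0",
                    r["seq"],
                    "I" * len(r["seq"]),
                ]
            )
        )
    return "\n".join(lines) + "\n"


def simulate_reads(
    genome: GenomeRef,
    models: Sequence[ExonModel],
    circles: Sequence[TruthCircle],
    decoys: Sequence[DecoySpec],
    params: SimParams,
    rng: Optional[np.random.Generator] = None,
) -> tuple[str, pd.DataFrame, pd.DataFrame, int]:
    """Emit the sample's SAM text plus the BSJ and event truth tables."""
    rng = rng if rng is not None else np.random.default_rng(params.seed + 1)
    records: list[dict] = []
    n_pairs = 0
    circle_spans = {(c.chrom, c.start, c.end): c for c in circles}
    for i, circle in enumerate(circles):
        n_pairs += reads_for_circle(rng, genome, circle, params, records, prefix=f"c{i:03d}")
    for decoy in decoys:
        circle = circle_spans.get((decoy.chrom, decoy.circle_start, decoy.circle_end))
        if circle is not None:
            n_pairs += _decoy_reads(genome, circle, decoy, params, records, prefix=f"x{decoy.donor}")
    circle_genes = {c.gene_name for c in circles}
    bg_models = [m for m in models if m.gene_name not in circle_genes]
    n_pairs += _background_reads(rng, genome, bg_models, params, records)

    truth_bsj = pd.DataFrame(
        [
            {"chrom": c.chrom, "start": c.start, "end": c.end, "strand": c.strand,
             "gene": c.gene_name}
            for c in circles
        ],
        columns=["chrom", "start", "end", "strand", "gene"],
    )
    truth_events = pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "circ_start": c.start,
                "circ_end": c.end,
                "event_type": etype,
                "alt_start": als,
                "alt_end": ale,
                "gene": c.gene_name,
            }
            for c in circles
            for (etype, als, ale) in c.planted_events
        ],
        columns=["chrom", "circ_start", "circ_end", "event_type", "alt_start", "alt_end", "gene"],
    )
    return _sam_text(genome, records), truth_bsj, truth_events, n_pairs


def simulate_bundle(params: Optional[SimParams] = None) -> SimBundle:
    """Full deterministic fixture bundle from one seed."""
    params = params or SimParams()
    rng = np.random.default_rng(params.seed)
    genome, models, circles, decoys = make_genome_and_annotation(params, rng)
    sam_text, truth_bsj, truth_events, n_pairs = simulate_reads(
        genome, models, circles, decoys, params, rng
    )
    return SimBundle(
        genome=genome,
        models=models,
        circles=list(circles),
        decoys=list(decoys),
        sam_text=sam_text,
        truth_bsj=truth_bsj,
        truth_events=truth_events,
        n_read_pairs=n_pairs,
    )


def write_bundle(bundle: SimBundle, outdir) -> dict[str, Path]:
    """Write the fixture bundle (FASTA/GTF/SAM + truth TSVs) to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "ref.fa",
        "gtf": outdir / "annotation.gtf",
        "sam": outdir / "reads.sam",
        "truth_bsj": outdir / "truth_bsj.tsv",
        "truth_events": outdir / "truth_events.tsv",
        "decoys": outdir / "decoys.tsv",
    }
    write_fasta(bundle.genome, paths["fasta"])
    write_gtf(bundle.models, paths["gtf"])
    paths["sam"].write_text(bundle.sam_text)
    bundle.truth_bsj.to_csv(paths["truth_bsj"], sep="\t", index=False)
    bundle.truth_events.to_csv(paths["truth_events"], sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "chrom": d.chrom,
                "donor": d.donor,
                "acceptor": d.acceptor,
                "kind": d.kind,
                "wb_alt_start": d.wb_alt_start,
                "wb_alt_end": d.wb_alt_end,
                "circle_start": d.circle_start,
                "circle_end": d.circle_end,
            }
            for d in bundle.decoys
        ],
        columns=[
            "chrom", "donor", "acceptor", "kind",
            "wb_alt_start", "wb_alt_end", "circle_start", "circle_end",
        ],
    ).to_csv(paths["decoys"], sep="\t", index=False)
    return paths


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def score_against_truth(events: Sequence, truth_events: pd.DataFrame) -> pd.DataFrame:
    """Per-type and overall precision/recall of detected events vs truth.

    Matching is by exact key (chrom, circle span, type, alternative segment).
    Precision is NaN when nothing of that type was detected; recall is NaN
    when nothing of that type was planted.
    """
    detected = {ev.key for ev in events}
    truth = {
        (r.chrom, int(r.circ_start), int(r.circ_end), r.event_type,
         int(r.alt_start), int(r.alt_end))
        for r in truth_events.itertuples(index=False)
    }
    rows = []
    types = list(dict.fromkeys([*_EVENT_CYCLE, "overall"]))
    for etype in types:
        if etype == "overall":
            det, tru = detected, truth
        else:
            det = {k for k in detected if k[3] == etype}
            tru = {k for k in truth if k[3] == etype}
        tp = len(det & tru)
        precision = tp / len(det) if det else float("nan")
        recall = tp / len(tru) if tru else float("nan")
        rows.append(
            {"event_type": etype, "tp": tp, "detected": len(det), "planted": len(tru),
             "precision": precision, "recall": recall}
        )
    return pd.DataFrame(rows).set_index("event_type")
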