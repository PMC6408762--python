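"""Alternative-splicing events inside circRNAs.

For each detected back-splice junction, the reads assigned to that circle
(BSJ-spanning reads plus their fully-internal mates) are scanned for
internal splice junctions.  Junctions must carry a canonical splice motif
and, unless correction is disabled, at least one boundary identical to an
annotated exon boundary.  Surviving junctions, together with read coverage
evidence and the exon annotation, are classified into the four event types:

SE    an internal exon present in one isoform, skipped in the other
RI    an intron spliced out in one isoform, retained (covered) in another
A5SS  two junctions sharing one boundary, differing at the 5' splice site
A3SS  likewise, differing at the 3' splice site

Every emitted event carries read support for both isoforms: an alternative
splicing call requires evidence that both forms exist in the sample.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .backsplice import (
    BackSpliceJunction,
    check_splice_motif,
    detect_bsj,
    find_bsj_candidates,
)
from .io import (
    AlignedRead,
    BIOTYPE_PRIORITY,
    ExonModel,
    GenomeRef,
    read_alignments,
    read_fasta,
    read_gtf,
)

log = logging.getLogger("circas")


@dataclass
class DetectParams:
    """Tunable thresholds of the per-sample detection pipeline."""

    min_bsj_support: int = 2
    min_intron_len: int = 30
    min_junction_support: int = 1
    min_overlap: int = 8
    correct: bool = True


@dataclass(frozen=True)
class InternalJunction:
    """One spliced junction internal to a circle, aggregated over reads."""

    chrom: str
    donor: int
    acceptor: int
    support: int
    motif_ok: bool
    corrected: bool
    read_ids: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(f"junction donor {self.donor} >= acceptor {self.acceptor}")


@dataclass
class CircASEvent:
    """One alternative-splicing event inside one circRNA."""

    circ: BackSpliceJunction
    event_type: str
    alt_start: int
    alt_end: int
    incl_reads: int
    excl_reads: int
    host_gene: str = "NA"
    host_biotype: str = "other"
    corrected: bool = True
    sample: str = "sample"
    # For A5SS/A3SS: the boundary the two junctions share, and on which side
    # of the alternative segment it lies ("right" = shared acceptor
    # downstream, "left" = shared donor upstream).  Used for the per-type
    # intron-length statistic.
    shared_site: Optional[int] = None
    pair_side: Optional[str] = None

    @property
    def alt_len(self) -> int:
        return self.alt_end - self.alt_start + 1

    @property
    def key(self) -> tuple:
        return (
            self.circ.chrom,
            self.circ.start,
            self.circ.end,
            self.event_type,
            self.alt_start,
            self.alt_end,
        )


class AnnotationIndex:
    """Lookup structures over exon models: boundaries, introns, exact exons."""

    def __init__(self, models: Sequence[ExonModel]):
        self.models = list(models)
        # boundary position -> list of (exon_start, exon_end, model)
        self.exon_ends: dict[str, dict[int, list]] = {}
        self.exon_starts: dict[str, dict[int, list]] = {}
        # (donor, acceptor) of annotated introns -> models
        self.introns: dict[str, dict[tuple[int, int], list]] = {}
        # exact exon span -> models
        self.exact_exons: dict[str, dict[tuple[int, int], list]] = {}
        # sorted exon list per chromosome for range queries
        self._exons_sorted: dict[str, list[tuple[int, int, ExonModel]]] = {}
        for m in models:
            ends = self.exon_ends.setdefault(m.chrom, {})
            starts = self.exon_starts.setdefault(m.chrom, {})
            introns = self.introns.setdefault(m.chrom, {})
            exact = self.exact_exons.setdefault(m.chrom, {})
            es = self._exons_sorted.setdefault(m.chrom, [])
            for i, (s, e) in enumerate(m.exons):
                ends.setdefault(e, []).append((s, e, m))
                starts.setdefault(s, []).append((s, e, m))
                exact.setdefault((s, e), []).append(m)
                es.append((s, e, m))
                if i + 1 < len(m.exons):
                    nxt = m.exons[i + 1]
                    introns.setdefault((e, nxt[0]), []).append(m)
        for es in self._exons_sorted.values():
            es.sort(key=lambda t: (t[0], t[1]))

    def matches_end(self, chrom: str, pos: int) -> bool:
        return pos in self.exon_ends.get(chrom, {})

    def matches_start(self, chrom: str, pos: int) -> bool:
        return pos in self.exon_starts.get(chrom, {})

    def exons_within(self, chrom: str, lo: int, hi: int) -> list[tuple[int, int, ExonModel]]:
        """Annotated exons (s, e) with lo < s <= e < hi."""
        es = self._exons_sorted.get(chrom, [])
        starts = [t[0] for t in es]
        i = bisect.bisect_right(starts, lo)
        out = []
        while i < len(es) and es[i][0] < hi:
            if es[i][1] < hi:
                out.append(es[i])
            i += 1
        return out


def resolve_host(
    index: AnnotationIndex,
    chrom: str,
    event_type: str,
    alt_start: int,
    alt_end: int,
    shared_site: Optional[int] = None,
) -> tuple[str, str]:
    """Host gene and biotype for an event via its correcting transcripts.

    Candidate transcripts are those whose annotated boundaries anchor the
    event (the skipped exon for SE, the intron for RI, any matching splice
    boundary for A5SS/A3SS).  Ties break mRNA > lncRNA > other, then by gene
    name for determinism.
    """
    cands: list[ExonModel] = []
    if event_type == "SE":
        cands = list(index.exact_exons.get(chrom, {}).get((alt_start, alt_end), []))
    elif event_type == "RI":
        cands = list(index.introns.get(chrom, {}).get((alt_start - 1, alt_end + 1), []))
    else:
        ends = index.exon_ends.get(chrom, {})
        starts = index.exon_starts.get(chrom, {})
        for pos in (alt_start - 1, alt_end):
            cands.extend(m for _, _, m in ends.get(pos, []))
        for pos in (alt_start, alt_end + 1):
            cands.extend(m for _, _, m in starts.get(pos, []))
        if shared_site is not None:
            cands.extend(m for _, _, m in ends.get(shared_site, []))
            cands.extend(m for _, _, m in starts.get(shared_site, []))
    if not cands:
        return "NA", "other"
    best = min(cands, key=lambda m: (BIOTYPE_PRIORITY.get(m.biotype, 2), m.gene_name))
    return best.gene_name, best.biotype


def assign_reads_to_circ(
    bsj: BackSpliceJunction, reads: Sequence[AlignedRead]
) -> list[AlignedRead]:
    """Reads belonging to one circle.

    (a) every read whose chimeric segments yield exactly this BSJ, and
    (b) every mate of such a read whose aligned blocks (including any
    supplementary segments) fall entirely within the circle span.
    """
    key = (bsj.chrom, bsj.start, bsj.end)
    by_mate: dict[tuple[str, int], AlignedRead] = {r.read_id: r for r in reads}
    spanning = [r for r in reads if find_bsj_candidates(r) == key]
    assigned: dict[tuple[str, int], AlignedRead] = {r.read_id: r for r in spanning}
    for r in spanning:
        mate = by_mate.get((r.read_name, 2 if r.mate_number == 1 else 1))
        if mate is None or mate.read_id in assigned:
            continue
        if all(
            chrom == bsj.chrom and bsj.start <= s and e <= bsj.end
            for chrom, s, e in mate.all_blocks()
        ):
            assigned[mate.read_id] = mate
    return list(assigned.values())


def extract_internal_junctions(
    reads: Sequence[AlignedRead],
    genome: GenomeRef,
    min_intron_len: int = 30,
    min_junction_support: int = 1,
) -> list[InternalJunction]:
    """Canonically-flanked junctions from inter-block gaps of assigned reads.

    A gap of at least ``min_intron_len`` between consecutive blocks of any
    aligned segment defines a (donor, acceptor) pair; junctions are
    aggregated by exact coordinates with distinct-read support, and only
    motif-passing junctions are returned.
    """
    support: dict[tuple[str, int, int], set] = {}
    for read in reads:
        for seg in read.segments():
            for (s1, e1), (s2, e2) in zip(seg.blocks, seg.blocks[1:]):
                if s2 - e1 - 1 >= min_intron_len:
                    support.setdefault((seg.chrom, e1, s2), set()).add(read.read_id)
    out = []
    for (chrom, donor, acceptor), ids in support.items():
        if len(ids) < min_junction_support:
            continue
        ok, _ = check_splice_motif(genome, chrom, donor, acceptor)
        if not ok:
            continue
        out.append(
            InternalJunction(
                chrom=chrom,
                donor=donor,
                acceptor=acceptor,
                support=len(ids),
                motif_ok=True,
                corrected=False,
                read_ids=frozenset(ids),
            )
        )
    out.sort(key=lambda j: (j.chrom, j.donor, j.acceptor))
    return out


def correct_junctions(
    junctions: Sequence[InternalJunction],
    index: AnnotationIndex,
    keep_uncorrected: bool = False,
) -> list[InternalJunction]:
    """Annotation-based exon correction.

    A junction is corrected when its donor equals an annotated exon end or
    its acceptor equals an annotated exon start (either side suffices).
    Junctions unmatched on both sides are discarded, unless
    ``keep_uncorrected`` (novel-exon exploration) retains them flagged.
    """
    out = []
    for j in junctions:
        corrected = index.matches_end(j.chrom, j.donor) or index.matches_start(
            j.chrom, j.acceptor
        )
        if not corrected and not keep_uncorrected:
            continue
        out.append(
            InternalJunction(
                chrom=j.chrom,
                donor=j.donor,
                acceptor=j.acceptor,
                support=j.support,
                motif_ok=j.motif_ok,
                corrected=corrected,
                read_ids=j.read_ids,
            )
        )
    return out


def _se_pattern_right(index: AnnotationIndex, chrom: str, d1: int, d2: int) -> bool:
    # a pair of junctions sharing an acceptor whose longer donor is the end of
    # an annotated exon lying strictly inside the pair gap is an exon-skipping
    # signature, not an alternative 5'/3' site
    return any(s > d1 for s, _, _ in index.exon_ends.get(chrom, {}).get(d2, []))


def _se_pattern_left(index: AnnotationIndex, chrom: str, a1: int, a2: int) -> bool:
    return any(e < a2 for _, e, _ in index.exon_starts.get(chrom, {}).get(a1, []))


def classify_events(
    junctions: Sequence[InternalJunction],
    reads: Sequence[AlignedRead],
    index: AnnotationIndex,
    circ: BackSpliceJunction,
    params: Optional[DetectParams] = None,
    sample: str = "sample",
) -> list[CircASEvent]:
    """Classify SE / RI / A5SS / A3SS events inside one circle.

    Junction-pair events (A5SS/A3SS) are named on the transcribed strand,
    which the back-splice motif fixes (GT..AG = plus, CT..AC = minus).  Pairs
    matching an annotated exon-skipping signature are left to the SE caller.
    Every event requires read support for both isoforms.
    """
    params = params or DetectParams()
    events: list[CircASEvent] = []
    jxn = [j for j in junctions if j.chrom == circ.chrom]
    jset = {(j.donor, j.acceptor): j for j in jxn}

    # --- junction pairs: alternative 5'/3' splice sites -------------------
    by_acceptor: dict[int, list[InternalJunction]] = {}
    by_donor: dict[int, list[InternalJunction]] = {}
    for j in jxn:
        by_acceptor.setdefault(j.acceptor, []).append(j)
        by_donor.setdefault(j.donor, []).append(j)

    for acceptor, group in by_acceptor.items():
        group = sorted(group, key=lambda j: j.donor)
        for i in range(len(group)):
            for k in range(i + 1, len(group)):
                j1, j2 = group[i], group[k]  # donors d1 < d2, shared acceptor
                if _se_pattern_right(index, circ.chrom, j1.donor, j2.donor):
                    continue
                etype = "A5SS" if circ.strand == "+" else "A3SS"
                events.append(
                    CircASEvent(
                        circ=circ,
                        event_type=etype,
                        alt_start=j1.donor + 1,
                        alt_end=j2.donor,
                        incl_reads=j2.support,
                        excl_reads=j1.support,
                        corrected=j1.corrected or j2.corrected,
                        sample=sample,
                        shared_site=acceptor,
                        pair_side="right",
                    )
                )
    for donor, group in by_donor.items():
        group = sorted(group, key=lambda j: j.acceptor)
        for i in range(len(group)):
            for k in range(i + 1, len(group)):
                j1, j2 = group[i], group[k]  # acceptors a1 < a2, shared donor
                if _se_pattern_left(index, circ.chrom, j1.acceptor, j2.acceptor):
                    continue
                etype = "A3SS" if circ.strand == "+" else "A5SS"
                events.append(
                    CircASEvent(
                        circ=circ,
                        event_type=etype,
                        alt_start=j1.acceptor,
                        alt_end=j2.acceptor - 1,
                        incl_reads=j1.support,
                        excl_reads=j2.support,
                        corrected=j1.corrected or j2.corrected,
                        sample=sample,
                        shared_site=donor,
                        pair_side="left",
                    )
                )

    # --- skipped exons ----------------------------------------------------
    for j in jxn:
        for s, e, _model in index.exons_within(circ.chrom, j.donor, j.acceptor):
            incl_ids: set = set()
            for (d, a), other in jset.items():
                if a == s or d == e:
                    incl_ids |= other.read_ids
            if not incl_ids:
                # fall back to coverage evidence: a read block reaching at
                # least min_overlap bases into the exon
                for read in reads:
                    for chrom, bs, be in read.all_blocks():
                        if chrom != circ.chrom:
                            continue
                        if min(be, e) - max(bs, s) + 1 >= params.min_overlap:
                            incl_ids.add(read.read_id)
                            break
            if incl_ids:
                events.append(
                    CircASEvent(
                        circ=circ,
                        event_type="SE",
                        alt_start=s,
                        alt_end=e,
                        incl_reads=len(incl_ids),
                        excl_reads=j.support,
                        corrected=True,
                        sample=sample,
                    )
                )

    # --- retained introns ---------------------------------------------------
    for j in jxn:
        if (j.donor, j.acceptor) not in index.introns.get(circ.chrom, {}):
            continue
        spanning: set = set()
        for read in reads:
            for chrom, bs, be in read.all_blocks():
                if chrom == circ.chrom and bs <= j.donor and be >= j.acceptor + 1:
                    spanning.add(read.read_id)
                    break
        if spanning:
            events.append(
                CircASEvent(
                    circ=circ,
                    event_type="RI",
                    alt_start=j.donor + 1,
                    alt_end=j.acceptor - 1,
                    incl_reads=len(spanning),
                    excl_reads=j.support,
                    corrected=True,
                    sample=sample,
                )
            )

    # containment, dual-isoform support, host assignment, deduplication
    final: dict[tuple, CircASEvent] = {}
    for ev in events:
        if not (circ.start <= ev.alt_start <= ev.alt_end <= circ.end):
            continue
        if ev.incl_reads < 1 or ev.excl_reads < 1:
            continue
        ev.host_gene, ev.host_biotype = resolve_host(
            index, circ.chrom, ev.event_type, ev.alt_start, ev.alt_end, ev.shared_site
        )
        k = (ev.event_type, ev.alt_start, ev.alt_end)
        if k not in final:
            final[k] = ev
    out = list(final.values())
    out.sort(key=lambda ev: (ev.alt_start, ev.alt_end, ev.event_type))
    return out


def call_sample(
    reads: Sequence[AlignedRead],
    genome: GenomeRef,
    models: Sequence[ExonModel],
    params: Optional[DetectParams] = None,
    sample: str = "sample",
) -> tuple[list[BackSpliceJunction], list[CircASEvent]]:
    """Full per-sample pipeline on parsed inputs.

    detection -> read assignment -> junction extraction -> correction ->
    classification; deterministic given inputs and parameters.
    """
    params = params or DetectParams()
    index = AnnotationIndex(models)
    bsjs = detect_bsj(reads, genome, min_bsj_support=params.min_bsj_support)

    # precompute candidate -> reads and mate lookup once
    cand_reads: dict[tuple[str, int, int], list[AlignedRead]] = {}
    by_mate = {r.read_id: r for r in reads}
    for r in reads:
        cand = find_bsj_candidates(r)
        if cand is not None:
            cand_reads.setdefault(cand, []).append(r)

    all_events: list[CircASEvent] = []
    for bsj in bsjs:
        spanning = cand_reads.get((bsj.chrom, bsj.start, bsj.end), [])
        assigned: dict[tuple[str, int], AlignedRead] = {r.read_id: r for r in spanning}
        for r in spanning:
            mate = by_mate.get((r.read_name, 2 if r.mate_number == 1 else 1))
            if mate is None or mate.read_id in assigned:
                continue
            if all(
                chrom == bsj.chrom and bsj.start <= s and e <= bsj.end
                for chrom, s, e in mate.all_blocks()
            ):
                assigned[mate.read_id] = mate
        circle_reads = list(assigned.values())
        junctions = extract_internal_junctions(
            circle_reads,
            genome,
            min_intron_len=params.min_intron_len,
            min_junction_support=params.min_junction_support,
        )
        junctions = correct_junctions(junctions, index, keep_uncorrected=not params.correct)
        all_events.extend(
            classify_events(junctions, circle_reads, index, bsj, params, sample=sample)
        )
    all_events.sort(
        key=lambda ev: (ev.circ.chrom, ev.circ.start, ev.circ.end, ev.alt_start, ev.event_type)
    )
    return bsjs, all_events


def detect_file(
    alignment_path,
    fasta_path,
    gtf_path,
    params: Optional[DetectParams] = None,
    sample: str = "sample",
) -> tuple[list[BackSpliceJunction], list[CircASEvent]]:
    """Path-based wrapper around :func:`call_sample`."""
    params = params or DetectParams()
    genome = read_fasta(fasta_path)
    models = read_gtf(gtf_path)
    reads = read_alignments(alignment_path, min_intron_len=params.min_intron_len)
    return call_sample(reads, genome, models, params=params, sample=sample)


def read_events_tsv(path) -> list[CircASEvent]:
    """Parse an events TSV (as written by :func:`circas.io.write_events`)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "host_gene": str})
    out = []
    for row in df.itertuples(index=False):
        circ = BackSpliceJunction(
            chrom=str(row.circ_chrom),
            start=int(row.circ_start),
            end=int(row.circ_end),
            strand=str(row.circ_strand),
            support=0,
            motif="",
        )
        out.append(
            CircASEvent(
                circ=circ,
                event_type=str(row.event_type),
                alt_start=int(row.alt_start),
                alt_end=int(row.alt_end),
                incl_reads=int(row.incl_reads),
                excl_reads=int(row.excl_reads),
                host_gene=str(row.host_gene),
                host_biotype=str(row.host_biotype),
                corrected=bool(row.corrected),
                sample=str(row.sample),
            )
        )
    return out
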