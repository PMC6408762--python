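"""Readers, writers and shared genomic domain types.

Coordinate convention: every in-memory coordinate is 1-based inclusive
(the native convention of GTF and SAM POS).  BED export converts to
0-based half-open exactly once, at the writing boundary.
"""

from __future__ import annotations

import gzip
import hashlib
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pysam
from Bio import SeqIO

log = logging.getLogger("circas")


class InputError(Exception):
    """Missing or unreadable input."""

    exit_code = 2


class FormatError(Exception):
    """Structurally invalid input content."""

    exit_code = 3


class ConfigError(Exception):
    """Inconsistent run configuration (labels, empty gene list, ...)."""

    exit_code = 4


# Annotation biotype strings collapsed to the three-way split used for
# host-transcript classification.
_BIOTYPE_MAP = {
    "protein_coding": "mRNA",
    "lncRNA": "lncRNA",
    "lincRNA": "lncRNA",
    "antisense": "lncRNA",
}
# reverse map used when emitting GTF
_BIOTYPE_EMIT = {"mRNA": "protein_coding", "lncRNA": "lincRNA", "other": "misc_RNA"}

BIOTYPE_PRIORITY = {"mRNA": 0, "lncRNA": 1, "other": 2}

EVENT_TYPES = ("SE", "RI", "A5SS", "A3SS")

EVENTS_COLUMNS = [
    "sample",
    "circ_chrom",
    "circ_start",
    "circ_end",
    "circ_strand",
    "event_type",
    "alt_start",
    "alt_end",
    "alt_len",
    "incl_reads",
    "excl_reads",
    "host_gene",
    "host_biotype",
    "corrected",
]

COMPARISON_COLUMNS = ["event_key", "n_samples_A", "n_samples_B", "class"]


def classify_biotype(raw: str) -> str:
    return _BIOTYPE_MAP.get(raw, "other")


@dataclass(frozen=True)
class GenomeRef:
    """Reference genome held in memory: chromosome name -> uppercase sequence."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        normalized = {
            name: (seq if seq.isupper() else seq.upper())
            for name, seq in self.sequences.items()
        }
        object.__setattr__(self, "sequences", normalized)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Return bases start..end (1-based inclusive)."""
        if chrom not in self.sequences:
            raise KeyError(f"unknown chromosome {chrom!r}")
        if not (1 <= start <= end <= len(self.sequences[chrom])):
            raise ValueError(
                f"coordinates {start}-{end} out of range for {chrom} "
                f"(length {len(self.sequences[chrom])})"
            )
        return self.sequences[chrom][start - 1 : end]


@dataclass(frozen=True)
class ExonModel:
    """One annotated transcript: an ordered exon chain with a biotype."""

    transcript_id: str
    gene_id: str
    gene_name: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    biotype: str = "other"

    def __post_init__(self) -> None:
        exons = tuple(sorted(tuple(e) for e in self.exons))
        if not exons:
            raise ValueError(f"{self.transcript_id}: transcript without exons")
        if self.strand not in "+-":
            raise ValueError(f"{self.transcript_id}: strand must be + or -")
        prev_end = 0
        for s, e in exons:
            if s > e:
                raise ValueError(f"{self.transcript_id}: exon start {s} > end {e}")
            if s <= prev_end:
                raise ValueError(f"{self.transcript_id}: overlapping/unsorted exons")
            prev_end = e
        object.__setattr__(self, "exons", exons)

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1] + 1, self.exons[i + 1][0] - 1)
            for i in range(len(self.exons) - 1)
        )


@dataclass(frozen=True)
class Segment:
    """One aligned segment of a read (the primary part or a supplementary one).

    ``read_offset`` is the number of read bases preceding this segment in the
    SAM stored orientation (i.e. the leading soft/hard clip).  ``query_len``
    is the number of read bases the segment consumes.
    """

    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    read_offset: int
    query_len: int

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]


@dataclass
class AlignedRead:
    """One read (one mate of a pair) with its chimeric segment evidence."""

    read_name: str
    chrom: str
    strand: str
    blocks: tuple[tuple[int, int], ...]
    clip5: int
    clip3: int
    mate_chrom: Optional[str] = None
    mate_start: Optional[int] = None
    supplementary: list[Segment] = field(default_factory=list)
    mate_number: int = 1
    query_len: int = 0

    @property
    def read_id(self) -> tuple[str, int]:
        return (self.read_name, self.mate_number)

    def primary_segment(self) -> Segment:
        return Segment(
            chrom=self.chrom,
            strand=self.strand,
            blocks=self.blocks,
            read_offset=self.clip5,
            query_len=self.query_len,
        )

    def segments(self) -> list[Segment]:
        return [self.primary_segment(), *self.supplementary]

    def all_blocks(self) -> list[tuple[str, int, int]]:
        out = [(self.chrom, s, e) for s, e in self.blocks]
        for seg in self.supplementary:
            out.extend((seg.chrom, s, e) for s, e in seg.blocks)
        return out


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path) -> GenomeRef:
    """Load a (possibly gzipped) FASTA into a :class:`GenomeRef`.

    Headers are truncated at the first whitespace; sequences are uppercased.
    A duplicate chromosome name is a fatal format error.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"FASTA not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    sequences: dict[str, str] = {}
    with opener(path, "rt") as handle:
        for record in SeqIO.parse(handle, "fasta"):
            name = record.id
            if name in sequences:
                raise FormatError(f"duplicate chromosome name {name!r} in {path}")
            sequences[name] = str(record.seq).upper()
    if not sequences:
        raise FormatError(f"no FASTA records in {path}")
    return GenomeRef(sequences)


def write_fasta(genome: GenomeRef, path, width: int = 60) -> None:
    with open(path, "w") as out:
        for name in genome.sequences:
            out.write(f">{name}\n")
            seq = genome.sequences[name]
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GTF
# ---------------------------------------------------------------------------

_ATTR_RE = re.compile(r'(\S+)\s+"([^"]*)"')


def read_gtf(path) -> list[ExonModel]:
    """Parse exon features of an Ensembl-dialect GTF into transcript models.

    Exons lacking a ``transcript_id`` are skipped with a warning; a file from
    which zero transcripts parse is a fatal format error.  The biotype comes
    from ``transcript_biotype`` (falling back to ``gene_biotype``) and is
    collapsed to mRNA / lncRNA / other.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"GTF not found: {path}")
    opener = gzip.open if path.suffix == ".gz" else open
    tx: dict[str, dict] = {}
    with opener(path, "rt") as handle:
        for lineno, line in enumerate(handle, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            if fields[2] != "exon":
                continue
            attrs = dict(_ATTR_RE.findall(fields[8]))
            tid = attrs.get("transcript_id")
            if not tid:
                log.warning("%s:%d: exon without transcript_id skipped", path, lineno)
                continue
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            rec = tx.setdefault(
                tid,
                {
                    "gene_id": attrs.get("gene_id", tid),
                    "gene_name": attrs.get("gene_name", attrs.get("gene_id", tid)),
                    "chrom": fields[0],
                    "strand": fields[6] if fields[6] in "+-" else "+",
                    "exons": [],
                    "biotype": classify_biotype(
                        attrs.get("transcript_biotype", attrs.get("gene_biotype", ""))
                    ),
                },
            )
            rec["exons"].append((start, end))
    if not tx:
        raise FormatError(f"no transcripts parsed from {path}")
    models = [
        ExonModel(
            transcript_id=tid,
            gene_id=rec["gene_id"],
            gene_name=rec["gene_name"],
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=tuple(rec["exons"]),
            biotype=rec["biotype"],
        )
        for tid, rec in tx.items()
    ]
    models.sort(key=lambda m: (m.chrom, m.exons[0][0], m.transcript_id))
    return models


def write_gtf(models: Sequence[ExonModel], path) -> None:
    with open(path, "w") as out:
        for m in models:
            raw_biotype = _BIOTYPE_EMIT.get(m.biotype, "misc_RNA")
            for s, e in m.exons:
                attrs = (
                    f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}"; '
                    f'gene_name "{m.gene_name}"; transcript_biotype "{raw_biotype}";'
                )
                out.write(
                    "\t".join(
                        [m.chrom, "circas_sim", "exon", str(s), str(e), ".", m.strand, ".", attrs]
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# SAM / BAM
# ---------------------------------------------------------------------------


def blocks_from_cigar(
    pos: int, cigartuples: Sequence[tuple[int, int]], min_intron_len: int
) -> tuple[tuple[int, int], ...]:
    """Reference blocks of an alignment starting at 1-based ``pos``.

    M/=/X extend the current block.  N and D gaps of at least
    ``min_intron_len`` close the block (junction candidates); shorter D/N are
    treated as deletions and absorbed into the block.
    """
    blocks: list[tuple[int, int]] = []
    bstart: Optional[int] = None
    ref = pos
    for op, ln in cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if bstart is None:
                bstart = ref
            ref += ln
        elif op in (2, 3):  # D, N consume reference
            if ln >= min_intron_len:
                if bstart is not None:
                    blocks.append((bstart, ref - 1))
                    bstart = None
                ref += ln
            else:
                if bstart is None:
                    bstart = ref
                ref += ln
        # I, S, H, P consume no reference
    if bstart is not None:
        blocks.append((bstart, ref - 1))
    return tuple(blocks)


def _cigar_clips(cigartuples: Sequence[tuple[int, int]]) -> tuple[int, int]:
    lead = 0
    trail = 0
    i = 0
    while i < len(cigartuples) and cigartuples[i][0] in (4, 5):
        lead += cigartuples[i][1]
        i += 1
    j = len(cigartuples) - 1
    while j > i and cigartuples[j][0] in (4, 5):
        trail += cigartuples[j][1]
        j -= 1
    return lead, trail


def _query_alen(cigartuples: Sequence[tuple[int, int]]) -> int:
    return sum(ln for op, ln in cigartuples if op in (0, 1, 7, 8))


def read_alignments(path, min_intron_len: int = 30) -> list[AlignedRead]:
    """Read SAM/BAM into :class:`AlignedRead` records.

    Unmapped and secondary records are dropped; supplementary records are
    attached to the primary record of the same read (same name and mate
    number), buffering by read name so the input need not be name-sorted.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"alignment file not found: {path}")
    primaries: dict[tuple[str, int], pysam.AlignedSegment] = {}
    supps: dict[tuple[str, int], list[pysam.AlignedSegment]] = {}
    order: list[tuple[str, int]] = []
    try:
        with pysam.AlignmentFile(str(path), check_sq=False) as af:
            for recno, rec in enumerate(af, 1):
                if rec.is_unmapped or rec.is_secondary:
                    continue
                key = (rec.query_name, 2 if rec.is_read2 else 1)
                if rec.is_supplementary:
                    supps.setdefault(key, []).append(rec)
                else:
                    if key not in primaries:
                        order.append(key)
                    primaries[key] = rec
    except (ValueError, OSError) as exc:
        raise FormatError(f"corrupt alignment record in {path}: {exc}") from exc

    reads: list[AlignedRead] = []
    for key in order:
        rec = primaries[key]
        cig = rec.cigartuples or []
        blocks = blocks_from_cigar(rec.reference_start + 1, cig, min_intron_len)
        if not blocks:
            continue
        clip5, clip3 = _cigar_clips(cig)
        supplementary = []
        for srec in supps.get(key, []):
            scig = srec.cigartuples or []
            sblocks = blocks_from_cigar(srec.reference_start + 1, scig, min_intron_len)
            if not sblocks:
                continue
            slead, _ = _cigar_clips(scig)
            supplementary.append(
                Segment(
                    chrom=srec.reference_name,
                    strand="-" if srec.is_reverse else "+",
                    blocks=sblocks,
                    read_offset=slead,
                    query_len=_query_alen(scig),
                )
            )
        supplementary.sort(key=lambda s: s.read_offset)
        reads.append(
            AlignedRead(
                read_name=key[0],
                chrom=rec.reference_name,
                strand="-" if rec.is_reverse else "+",
                blocks=blocks,
                clip5=clip5,
                clip3=clip3,
                mate_chrom=rec.next_reference_name,
                mate_start=(rec.next_reference_start + 1)
                if rec.next_reference_start is not None and rec.next_reference_start >= 0
                else None,
                supplementary=supplementary,
                mate_number=key[1],
                query_len=_query_alen(cig),
            )
        )
    return reads


# ---------------------------------------------------------------------------
# TSV / BED output
# ---------------------------------------------------------------------------


def write_events(events: Sequence, path) -> None:
    """Write the per-sample events table (TSV, 1-based inclusive coordinates).

    Rows are sorted by (chrom, circ start, event start, type) so that
    identical inputs always produce byte-identical files.
    """
    rows = sorted(
        events,
        key=lambda ev: (
            ev.circ.chrom,
            ev.circ.start,
            ev.circ.end,
            ev.alt_start,
            ev.alt_end,
            ev.event_type,
            ev.sample,
        ),
    )
    with open(path, "w") as out:
        out.write("\t".join(EVENTS_COLUMNS) + "\n")
        for ev in rows:
            out.write(
                "\t".join(
                    str(x)
                    for x in (
                        ev.sample,
                        ev.circ.chrom,
                        ev.circ.start,
                        ev.circ.end,
                        ev.circ.strand,
                        ev.event_type,
                        ev.alt_start,
                        ev.alt_end,
                        ev.alt_len,
                        ev.incl_reads,
                        ev.excl_reads,
                        ev.host_gene,
                        ev.host_biotype,
                        1 if ev.corrected else 0,
                    )
                )
                + "\n"
            )


def format_event_key(key: tuple) -> str:
    chrom, cs, ce, etype, als, ale = key
    return f"{chrom}:{cs}-{ce}:{etype}:{als}-{ale}"


def parse_event_key(text: str) -> tuple:
    chrom, span, etype, alt = text.split(":")
    cs, ce = span.split("-")
    als, ale = alt.split("-")
    return (chrom, int(cs), int(ce), etype, int(als), int(ale))


def write_comparison(records: Sequence, path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(COMPARISON_COLUMNS) + "\n")
        for rec in records:
            out.write(
                "\t".join(
                    [
                        format_event_key(rec.event_key),
                        str(len(rec.samples_A)),
                        str(len(rec.samples_B)),
                        rec.cls,
                    ]
                )
                + "\n"
            )


def write_bsj_bed(bsjs: Sequence, path) -> None:
    """circRNA spans as BED6 (the single 1-based -> 0-based conversion point)."""
    with open(path, "w") as out:
        for b in sorted(bsjs, key=lambda b: (b.chrom, b.start, b.end)):
            out.write(
                "\t".join(
                    [
                        b.chrom,
                        str(b.start - 1),
                        str(b.end),
                        f"{b.chrom}:{b.start}-{b.end}",
                        str(b.support),
                        b.strand,
                    ]
                )
                + "\n"
            )


def md5sum(path) -> str:
    h = hashlib.md5()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
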