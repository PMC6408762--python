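"""Back-splice junction (BSJ) detection from chimeric read evidence.

A circRNA leaves a diagnostic head-to-tail junction: a read crossing it
aligns as two segments in inverted genomic order (the part later in the read
maps upstream of the earlier part).  Candidates are grouped by exact
coordinates and kept only when flanked by a canonical splice motif
(GT..AG read on the plus strand, CT..AC for minus-strand transcription) and
supported by enough distinct reads.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional

from .io import AlignedRead, GenomeRef

log = logging.getLogger("circas")

CANONICAL_MOTIFS = {"GTAG": "+", "CTAC": "-"}

#: tolerated slack (bases) between the read offsets of two chimeric segments
READ_OFFSET_TOLERANCE = 2


@dataclass(frozen=True)
class BackSpliceJunction:
    """One circRNA candidate: 5' end (acceptor side) < 3' end (donor side)."""

    chrom: str
    start: int
    end: int
    strand: str
    support: int
    motif: str

    @property
    def span(self) -> int:
        return self.end - self.start + 1


def check_splice_motif(
    genome: GenomeRef, chrom: str, donor_end: int, acceptor_start: int
) -> tuple[bool, str]:
    """Canonical splice-site check for a (donor, acceptor) junction.

    ``donor_end`` is the last exonic base on the donor side and
    ``acceptor_start`` the first exonic base on the acceptor side; the two
    intronic dinucleotides just outside them must read GT..AG (plus-strand
    transcription) or CT..AC (minus).  For a back-splice the donor lies
    genomically *downstream* of the acceptor; the same flanks apply.
    """
    length = genome.length(chrom)
    if donor_end + 2 > length or acceptor_start - 2 < 1:
        log.warning(
            "junction %s:%d-%d within 2 bp of chromosome edge", chrom, donor_end, acceptor_start
        )
        return False, ""
    motif = genome.fetch(chrom, donor_end + 1, donor_end + 2) + genome.fetch(
        chrom, acceptor_start - 2, acceptor_start - 1
    )
    return motif in CANONICAL_MOTIFS, motif


def find_bsj_candidates(read: AlignedRead) -> Optional[tuple[str, int, int]]:
    """Back-splice candidate from one read's chimeric segments, if any.

    Requires two segments on the same chromosome and strand whose read
    offsets are contiguous (within +/-2 bases) and whose genomic order is
    inverted relative to their read order.  Offsets are measured in SAM
    stored orientation, under which "later in the stored read maps strictly
    upstream" characterizes a back-splice on either strand.
    """
    if not read.supplementary:
        return None
    segs = sorted(read.segments(), key=lambda s: s.read_offset)
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            a, b = segs[i], segs[j]
            if a.chrom != b.chrom or a.strand != b.strand:
                continue
            if abs(b.read_offset - (a.read_offset + a.query_len)) > READ_OFFSET_TOLERANCE:
                continue
            if b.end < a.start:
                return (a.chrom, b.start, a.end)
    return None


def aggregate_bsj(
    candidates: Iterable[tuple[str, int, int, tuple]],
    genome: GenomeRef,
    min_bsj_support: int = 2,
) -> list[BackSpliceJunction]:
    """Group per-read candidates into motif-filtered, support-filtered BSJs.

    ``candidates`` yields (chrom, start, end, read_id).  Grouping is by exact
    coordinates; the strand is assigned by which canonical motif matched.
    """
    grouped: dict[tuple[str, int, int], set] = {}
    for chrom, start, end, read_id in candidates:
        grouped.setdefault((chrom, start, end), set()).add(read_id)
    out: list[BackSpliceJunction] = []
    for (chrom, start, end), read_ids in grouped.items():
        if len(read_ids) < min_bsj_support:
            continue
        ok, motif = check_splice_motif(genome, chrom, donor_end=end, acceptor_start=start)
        if not ok:
            continue
        out.append(
            BackSpliceJunction(
                chrom=chrom,
                start=start,
                end=end,
                strand=CANONICAL_MOTIFS[motif],
                support=len(read_ids),
                motif=motif,
            )
        )
    out.sort(key=lambda b: (b.chrom, b.start, b.end))
    return out


def detect_bsj(
    reads: Iterable[AlignedRead], genome: GenomeRef, min_bsj_support: int = 2
) -> list[BackSpliceJunction]:
    """Run candidate extraction over all reads of a sample and aggregate."""
    cands = []
    for read in reads:
        cand = find_bsj_candidates(read)
        if cand is not None:
            cands.append((*cand, read.read_id))
    return aggregate_bsj(cands, genome, min_bsj_support=min_bsj_support)
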