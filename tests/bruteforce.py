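"""Independent brute-force reference for BSJ and event detection.

Deliberately naive: exhaustive enumeration over every pair of aligned
segments, every pair of junctions, every annotated exon and intron, with no
indexing or grouping machinery shared with the package implementation.
Used as the oracle in equivalence tests on small fixtures.
"""

from __future__ import annotations

OFFSET_TOL = 2


def _segments(read):
    return sorted(read.segments(), key=lambda s: s.read_offset)


def brute_read_candidates(read):
    """All back-splice candidates of one read (exhaustive segment pairs)."""
    out = set()
    segs = _segments(read)
    for a in segs:
        for b in segs:
            if b.read_offset <= a.read_offset or a.chrom != b.chrom or a.strand != b.strand:
                continue
            if abs(b.read_offset - a.read_offset - a.query_len) > OFFSET_TOL:
                continue
            if b.blocks[-1][1] < a.blocks[0][0]:
                out.add((a.chrom, b.blocks[0][0], a.blocks[-1][1]))
    return out


def _motif(genome, chrom, donor, acceptor):
    seq = genome.sequences[chrom]
    if donor + 2 > len(seq) or acceptor - 3 < 0:
        return None
    return seq[donor : donor + 2] + seq[acceptor - 3 : acceptor - 1]


def brute_bsj(reads, genome, min_support=2):
    """Reference BSJ set: {(chrom, start, end, strand, support)}."""
    votes = {}
    for read in reads:
        for cand in brute_read_candidates(read):
            votes.setdefault(cand, set()).add((read.read_name, read.mate_number))
    out = set()
    for (chrom, start, end), ids in votes.items():
        if len(ids) < min_support:
            continue
        motif = _motif(genome, chrom, end, start)
        if motif == "GTAG":
            out.add((chrom, start, end, "+", len(ids)))
        elif motif == "CTAC":
            out.add((chrom, start, end, "-", len(ids)))
    return out


def _assigned(bsj_key, reads):
    chrom, start, end = bsj_key
    members = {}
    for read in reads:
        if bsj_key in brute_read_candidates(read):
            members[(read.read_name, read.mate_number)] = read
    for read in list(members.values()):
        for other in reads:
            if other.read_name != read.read_name or other.mate_number == read.mate_number:
                continue
            inside = all(
                c == chrom and start <= s and e <= end for c, s, e in other.all_blocks()
            )
            if inside:
                members.setdefault((other.read_name, other.mate_number), other)
    return list(members.values())


def brute_events(reads, genome, models, bsj_keys, min_intron_len=30, min_overlap=8,
                 correct=True):
    """Reference event-key set for the given circles.

    Returns {(chrom, circ_start, circ_end, type, alt_start, alt_end)}.
    """
    out = set()
    for chrom, start, end, strand in bsj_keys:
        members = _assigned((chrom, start, end), reads)
        jxn = {}
        for read in members:
            for seg in read.segments():
                for i in range(len(seg.blocks) - 1):
                    d = seg.blocks[i][1]
                    a = seg.blocks[i + 1][0]
                    if a - d - 1 >= min_intron_len:
                        jxn.setdefault((seg.chrom, d, a), set()).add(
                            (read.read_name, read.mate_number)
                        )
        kept = {}
        for (jchrom, d, a), ids in jxn.items():
            if jchrom != chrom:
                continue
            if _motif(genome, jchrom, d, a) not in ("GTAG", "CTAC"):
                continue
            if correct:
                anchored = False
                for m in models:
                    if m.chrom != chrom:
                        continue
                    for s, e in m.exons:
                        if e == d or s == a:
                            anchored = True
                if not anchored:
                    continue
            kept[(d, a)] = ids

        junctions = sorted(kept)

        def exon_skipping_right(d1, d2):
            for m in models:
                if m.chrom != chrom:
                    continue
                for s, e in m.exons:
                    if e == d2 and s > d1:
                        return True
            return False

        def exon_skipping_left(a1, a2):
            for m in models:
                if m.chrom != chrom:
                    continue
                for s, e in m.exons:
                    if s == a1 and e < a2:
                        return True
            return False

        for d1, a1 in junctions:
            for d2, a2 in junctions:
                if a1 == a2 and d1 < d2 and not exon_skipping_right(d1, d2):
                    etype = "A5SS" if strand == "+" else "A3SS"
                    if start <= d1 + 1 and d2 <= end:
                        out.add((chrom, start, end, etype, d1 + 1, d2))
                if d1 == d2 and a1 < a2 and not exon_skipping_left(a1, a2):
                    etype = "A3SS" if strand == "+" else "A5SS"
                    if start <= a1 and a2 - 1 <= end:
                        out.add((chrom, start, end, etype, a1, a2 - 1))

        for d, a in junctions:
            # skipped exons
            for m in models:
                if m.chrom != chrom:
                    continue
                for s, e in m.exons:
                    if not (d < s <= e < a):
                        continue
                    incl = False
                    for (dd, aa), _ids in kept.items():
                        if aa == s or dd == e:
                            incl = True
                    if not incl:
                        for read in members:
                            for c, bs, be in read.all_blocks():
                                if c == chrom and min(be, e) - max(bs, s) + 1 >= min_overlap:
                                    incl = True
                    if incl and start <= s and e <= end:
                        out.add((chrom, start, end, "SE", s, e))
            # retained introns
            annotated_intron = False
            for m in models:
                if m.chrom != chrom:
                    continue
                for i in range(len(m.exons) - 1):
                    if m.exons[i][1] == d and m.exons[i + 1][0] == a:
                        annotated_intron = True
            if not annotated_intron:
                continue
            for read in members:
                if any(
                    c == chrom and bs <= d and be >= a + 1 for c, bs, be in read.all_blocks()
                ):
                    if start <= d + 1 and a - 1 <= end:
                        out.add((chrom, start, end, "RI", d + 1, a - 1))
                    break
    return out
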