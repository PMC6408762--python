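"""Cross-sample comparison and characterization of circ-AS catalogs.

Events are keyed by exact coordinates (chrom, circle span, type, alternative
segment); presence/absence across two conditions partitions the catalog into
condition-A-specific, condition-B-specific and common classes.  The summary
statistics mirror the standard characterization of such catalogs: per-class
event-type proportions, per-type mean flanking-intron length with its
standard error, the mRNA/lncRNA host split, and per-gene occurrence counts
against a user gene list (e.g. oncogenes or tumor suppressors).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .events import AnnotationIndex, CircASEvent, resolve_host
from .io import ConfigError, EVENT_TYPES, ExonModel

log = logging.getLogger("circas")

CLASSES = ("A_specific", "B_specific", "common")


@dataclass(frozen=True)
class ComparisonRecord:
    """One event key with per-condition sample presence and its class."""

    event_key: tuple
    samples_A: tuple[str, ...]
    samples_B: tuple[str, ...]
    cls: str


@dataclass
class SummaryTable:
    """Per-class characterization of a compared event catalog."""

    type_counts: pd.DataFrame      # class x event type -> count
    type_percent: pd.DataFrame     # class x event type -> % within class
    intron_length: pd.DataFrame    # (class, type) -> mean / se / n
    biotype_counts: pd.DataFrame   # class x {mRNA, lncRNA, other} -> count
    biotype_percent: pd.DataFrame  # class x {mRNA, lncRNA} -> % of two-way split

    def to_text(self) -> str:
        lines = ["# Event-type counts per class", self.type_counts.to_string(), ""]
        lines += ["# Event-type percentages per class", self.type_percent.round(1).to_string(), ""]
        lines += ["# Mean circ-AS intron length (bp) per class and type",
                  self.intron_length.round(1).to_string(), ""]
        lines += ["# Host biotype counts per class", self.biotype_counts.to_string(), ""]
        lines += ["# Host biotype percentages (mRNA/lncRNA split) per class",
                  self.biotype_percent.round(1).to_string(), ""]
        return "\n".join(lines)


def _merge_keys(keys: Sequence[tuple], window: int) -> dict[tuple, tuple]:
    """Map each key to a cluster representative under a coordinate window.

    Keys of the same chromosome and type whose circle and alternative-segment
    coordinates all differ by at most ``window`` chain into one cluster; the
    representative is the smallest key of the cluster.  ``window == 0`` is
    the identity map.
    """
    if window <= 0:
        return {k: k for k in keys}
    rep: dict[tuple, tuple] = {}
    ordered = sorted(keys)
    clusters: list[tuple] = []
    for key in ordered:
        chrom, cs, ce, etype, als, ale = key
        assigned = None
        for ck in reversed(clusters):
            if ck[0] != chrom or ck[3] != etype:
                continue
            if (
                abs(cs - ck[1]) <= window
                and abs(ce - ck[2]) <= window
                and abs(als - ck[4]) <= window
                and abs(ale - ck[5]) <= window
            ):
                assigned = ck
                break
        if assigned is None:
            clusters.append(key)
            assigned = key
        rep[key] = assigned
    return rep


def compare_conditions(
    events_by_sample: Mapping[str, Sequence[CircASEvent]],
    labels: Mapping[str, str],
    merge_window: int = 0,
) -> list[ComparisonRecord]:
    """Partition the union of event keys into A-specific / B-specific / common.

    ``labels`` maps each sample id to condition "A" or "B".  A sample present
    in the events but missing from the labels is a configuration error.
    """
    for sample in events_by_sample:
        if sample not in labels:
            raise ConfigError(f"sample {sample!r} has no condition label")
        if labels[sample] not in ("A", "B"):
            raise ConfigError(f"label for {sample!r} must be 'A' or 'B'")
    if "A" not in set(labels.values()) or "B" not in set(labels.values()):
        raise ConfigError("need at least one sample per condition")

    all_keys = sorted({ev.key for evs in events_by_sample.values() for ev in evs})
    rep = _merge_keys(all_keys, merge_window)

    presence: dict[tuple, dict[str, set]] = {}
    for sample, evs in events_by_sample.items():
        cond = labels[sample]
        for ev in evs:
            entry = presence.setdefault(rep[ev.key], {"A": set(), "B": set()})
            entry[cond].add(sample)

    records = []
    for key in sorted(presence):
        a = tuple(sorted(presence[key]["A"]))
        b = tuple(sorted(presence[key]["B"]))
        if a and b:
            cls = "common"
        elif a:
            cls = "A_specific"
        else:
            cls = "B_specific"
        records.append(ComparisonRecord(event_key=key, samples_A=a, samples_B=b, cls=cls))
    return records


def circ_as_intron_length(
    event: CircASEvent, models: Optional[Sequence[ExonModel]] = None
) -> Optional[int]:
    """Flanking-intron length statistic for one event, in bp.

    RI: the retained intron's own length.  A5SS/A3SS: the length of the
    intron remaining between the longer splice variant and the shared
    boundary.  SE: the mean of the skipped exon's two flanking intron
    lengths in the host transcript (None when no host transcript is known).
    """
    if event.event_type == "RI":
        return event.alt_len
    if event.event_type in ("A5SS", "A3SS"):
        if event.shared_site is None or event.pair_side is None:
            return None
        if event.pair_side == "right":
            return event.shared_site - event.alt_end - 1
        return event.alt_start - event.shared_site - 1
    # SE: locate the skipped exon in a host transcript with both neighbours
    if models is None:
        return None
    for m in models:
        if m.chrom != event.circ.chrom:
            continue
        if event.host_gene not in ("NA", None) and m.gene_name != event.host_gene:
            continue
        for i, (s, e) in enumerate(m.exons):
            if (s, e) == (event.alt_start, event.alt_end) and 0 < i < len(m.exons) - 1:
                up = s - m.exons[i - 1][1] - 1
                down = m.exons[i + 1][0] - e - 1
                return int(round((up + down) / 2))
    return None


def host_biotype(event: CircASEvent, models: Sequence[ExonModel]) -> str:
    """Biotype of the transcript that corrected the event's junctions.

    Ties break mRNA > lncRNA > other (a coding-gene overlap dominates);
    "other" when no correcting transcript exists.
    """
    index = AnnotationIndex(models)
    _, biotype = resolve_host(
        index,
        event.circ.chrom,
        event.event_type,
        event.alt_start,
        event.alt_end,
        event.shared_site,
    )
    return biotype


def index_events(
    events_by_sample: Mapping[str, Sequence[CircASEvent]]
) -> dict[tuple, CircASEvent]:
    """One representative event per key (first by sorted sample id)."""
    out: dict[tuple, CircASEvent] = {}
    for sample in sorted(events_by_sample):
        for ev in events_by_sample[sample]:
            out.setdefault(ev.key, ev)
    return out


def overlap_gene_list(
    records: Sequence[ComparisonRecord],
    events_by_key: Mapping[tuple, CircASEvent],
    gene_list: Iterable[str],
    cls: str = "A_specific",
) -> pd.DataFrame:
    """Per-gene, per-type occurrence counts restricted to one class.

    Gene symbols match case-insensitively on the event host gene.  The
    result is the machine-readable form of a gene-list occurrence panel
    (e.g. oncogenes hosting condition-specific events).
    """
    genes = {g.strip().upper() for g in gene_list if g.strip()}
    if not genes:
        raise ConfigError("gene list is empty")
    counts: dict[str, dict[str, int]] = {}
    for rec in records:
        if rec.cls != cls:
            continue
        ev = events_by_key.get(rec.event_key)
        if ev is None:
            continue
        gene = (ev.host_gene or "NA").upper()
        if gene not in genes:
            continue
        counts.setdefault(ev.host_gene, {t: 0 for t in EVENT_TYPES})
        counts[ev.host_gene][ev.event_type] += 1
    df = pd.DataFrame.from_dict(counts, orient="index", columns=list(EVENT_TYPES))
    if df.empty:
        df = pd.DataFrame(columns=list(EVENT_TYPES))
    df = df.fillna(0).astype(int).sort_index()
    df.index.name = "gene"
    return df


def summarize(
    records: Sequence[ComparisonRecord],
    events_by_key: Mapping[tuple, CircASEvent],
    models: Optional[Sequence[ExonModel]] = None,
) -> SummaryTable:
    """Per-class characterization table.

    Percentages are carried at full precision (rounded only for display).
    The mRNA/lncRNA percentage split excludes "other" hosts, which are
    counted separately.  Intron-length means come with the standard error
    of the mean (sample SD / sqrt(n)).
    """
    type_counts = pd.DataFrame(0, index=list(CLASSES), columns=list(EVENT_TYPES))
    biotype_counts = pd.DataFrame(0, index=list(CLASSES), columns=["mRNA", "lncRNA", "other"])
    lengths: dict[tuple[str, str], list[int]] = {}
    for rec in records:
        ev = events_by_key.get(rec.event_key)
        if ev is None:
            continue
        type_counts.loc[rec.cls, ev.event_type] += 1
        biotype_counts.loc[rec.cls, ev.host_biotype] += 1
        L = circ_as_intron_length(ev, models)
        if L is not None:
            lengths.setdefault((rec.cls, ev.event_type), []).append(L)

    totals = type_counts.sum(axis=1)
    type_percent = type_counts.div(totals.replace(0, np.nan), axis=0) * 100.0
    type_percent = type_percent.fillna(0.0)

    two_way = biotype_counts[["mRNA", "lncRNA"]]
    two_tot = two_way.sum(axis=1)
    biotype_percent = two_way.div(two_tot.replace(0, np.nan), axis=0) * 100.0
    biotype_percent = biotype_percent.fillna(0.0)

    rows = []
    for cls in CLASSES:
        for etype in EVENT_TYPES:
            vals = lengths.get((cls, etype), [])
            n = len(vals)
            mean = float(np.mean(vals)) if n else np.nan
            se = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
            rows.append({"class": cls, "event_type": etype, "mean": mean, "se": se, "n": n})
    intron_length = pd.DataFrame(rows).set_index(["class", "event_type"])

    return SummaryTable(
        type_counts=type_counts,
        type_percent=type_percent,
        intron_length=intron_length,
        biotype_counts=biotype_counts,
        biotype_percent=biotype_percent,
    )
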