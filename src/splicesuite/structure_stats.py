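"""Annotation-referenced structural characterization of splicing events.

Three families of statistics over significant skipped-exon (and
retained-intron) events:

* which skip junctions are absent from the annotation (novel splicing),
* how many annotated exon loci each skip junction jumps over
  (single- vs multi-exon skipping),
* the sizes of the flanking exons, flanking introns and the skipped exon
  (or retained intron), with annotated-transcriptome baselines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .annotation import JunctionIndex
from .rmats_io import (
    ASType,
    RIEventView,
    SEEventView,
    SpliceEvent,
    event_key,
)

HISTOGRAM_BINS = ("0", "1", "2", "3", ">=4")


@dataclass(frozen=True)
class AnnotationStatus:
    event_key: str
    gene_symbol: str
    skip_junction: tuple[str, str, int, int]
    annotated: bool
    fdr: float


@dataclass
class AnnotationSummary:
    total: int
    annotated: int
    statuses: list[AnnotationStatus]

    @property
    def unannotated(self) -> int:
        return self.total - self.annotated

    @property
    def fraction_unannotated(self) -> float | None:
        return (self.unannotated / self.total) if self.total else None


def _se_views(events: Iterable[SpliceEvent]) -> list[SEEventView]:
    views = []
    for ev in events:
        if ev.as_type is not ASType.SE:
            raise ValueError(f"expected SE events, got {ev.as_type}")
        v = SEEventView(ev)
        v.validate()
        views.append(v)
    return views


def classify_annotation(
    events: Iterable[SpliceEvent], index: JunctionIndex, fuzz: int = 0
) -> AnnotationSummary:
    """Mark each SE event's skip junction as annotated or novel.

    A skip junction is annotated iff the intron (upstream exon end,
    downstream exon start) appears between consecutive exons of some
    annotated transcript on the same chromosome and strand — exactly by
    default, or within ±``fuzz`` nt at both ends for annotation dialects
    with off-by-one boundaries.
    """
    statuses = []
    for view in _se_views(events):
        junction = view.skip_junction
        statuses.append(
            AnnotationStatus(
                event_key=event_key(view.event),
                gene_symbol=view.event.gene_symbol,
                skip_junction=junction,
                annotated=index.has_intron(*junction, fuzz=fuzz),
                fdr=view.event.fdr,
            )
        )
    return AnnotationSummary(
        total=len(statuses),
        annotated=sum(s.annotated for s in statuses),
        statuses=statuses,
    )


def count_intervening_exons(view: SEEventView, index: JunctionIndex) -> int:
    """Number of annotated exon loci strictly inside the skip junction.

    Exon intervals fully contained in the open skip intron are merged into
    overlap clusters (isoform end variation collapses to one locus); the
    cluster count is returned.
    """
    chrom, strand, start, end = view.skip_junction
    if end <= start:
        raise ValueError(f"degenerate skip junction [{start}, {end})")
    contained = index.exons_within(chrom, strand, start, end)
    clusters = 0
    cur_end = -1
    for s, e in contained:  # sorted by start
        if s >= cur_end:
            clusters += 1
            cur_end = e
        else:
            cur_end = max(cur_end, e)
    return clusters


@dataclass(frozen=True)
class SkipCountRecord:
    event_key: str
    gene_symbol: str
    n_intervening: int


def number_skipped_summary(
    events: Iterable[SpliceEvent], index: JunctionIndex
) -> tuple[dict[str, int], list[SkipCountRecord]]:
    """Histogram of intervening-exon counts over bins 0 / 1 / 2 / 3 / >=4.

    Bin 0 collects events whose skip junction contains no annotated exon
    at all (an entirely novel skipped exon); the histogram always sums to
    the event count.
    """
    hist = {b: 0 for b in HISTOGRAM_BINS}
    records = []
    for view in _se_views(events):
        n = count_intervening_exons(view, index)
        records.append(
            SkipCountRecord(
                event_key=event_key(view.event),
                gene_symbol=view.event.gene_symbol,
                n_intervening=n,
            )
        )
        hist[">=4" if n >= 4 else str(n)] += 1
    return hist, records


@dataclass(frozen=True)
class SESizeRecord:
    """Transcript-oriented sizes (nt) for one skipped-exon configuration."""

    event_key: str
    upstream_exon_len: int
    upstream_intron_len: int
    skipped_exon_len: int
    downstream_intron_len: int
    downstream_exon_len: int

    def as_tuple(self) -> tuple[int, int, int, int, int]:
        return (
            self.upstream_exon_len,
            self.upstream_intron_len,
            self.skipped_exon_len,
            self.downstream_intron_len,
            self.downstream_exon_len,
        )


SE_SIZE_FIELDS = (
    "upstream_exon_len",
    "upstream_intron_len",
    "skipped_exon_len",
    "downstream_intron_len",
    "downstream_exon_len",
)

RI_SIZE_FIELDS = ("upstream_exon_len", "retained_intron_len", "downstream_exon_len")


def _se_sizes_from_parts(
    strand: str,
    left_exon: tuple[int, int],
    mid_exon: tuple[int, int],
    right_exon: tuple[int, int],
    key: str,
) -> SESizeRecord:
    left_intron = mid_exon[0] - left_exon[1]
    right_intron = right_exon[0] - mid_exon[1]
    if strand == "+":
        up_e, up_i, dn_i, dn_e = (
            left_exon[1] - left_exon[0],
            left_intron,
            right_intron,
            right_exon[1] - right_exon[0],
        )
    else:  # transcript orientation: genomic-right is upstream
        up_e, up_i, dn_i, dn_e = (
            right_exon[1] - right_exon[0],
            right_intron,
            left_intron,
            left_exon[1] - left_exon[0],
        )
    return SESizeRecord(
        event_key=key,
        upstream_exon_len=up_e,
        upstream_intron_len=up_i,
        skipped_exon_len=mid_exon[1] - mid_exon[0],
        downstream_intron_len=dn_i,
        downstream_exon_len=dn_e,
    )


def se_size_record(view: SEEventView) -> SESizeRecord:
    return _se_sizes_from_parts(
        view.event.strand,
        (view.left_es, view.left_ee),
        (view.exon_start, view.exon_end),
        (view.right_es, view.right_ee),
        event_key(view.event),
    )


def _mean_columns(records: Sequence[tuple[int, ...]], width: int) -> list[float]:
    if not records:
        return [math.nan] * width
    return [sum(r[i] for r in records) / len(records) for i in range(width)]


def se_intron_exon_sizes(
    events: Iterable[SpliceEvent],
    annotated_triples: Sequence[tuple] = (),
) -> tuple[list[SESizeRecord], list[float], list[float]]:
    """Per-event SE size records plus event means and annotated baseline means.

    ``annotated_triples`` is the output of
    :func:`~splicesuite.annotation.enumerate_annotated_se_triples`; its
    means are the "Annotated" reference line.
    """
    records = [se_size_record(v) for v in _se_views(events)]
    event_means = _mean_columns([r.as_tuple() for r in records], 5)

    base_rows = []
    for chrom, strand, up, mid, dn in annotated_triples:
        left, right = (up, dn) if strand == "+" else (dn, up)
        base_rows.append(
            _se_sizes_from_parts(strand, left, mid, right, "annotated").as_tuple()
        )
    baseline_means = _mean_columns(base_rows, 5)
    return records, event_means, baseline_means


@dataclass(frozen=True)
class RISizeRecord:
    event_key: str
    upstream_exon_len: int
    retained_intron_len: int
    downstream_exon_len: int

    def as_tuple(self) -> tuple[int, int, int]:
        return (self.upstream_exon_len, self.retained_intron_len, self.downstream_exon_len)


def ri_size_record(view: RIEventView) -> RISizeRecord:
    up = view.upstream_exon
    dn = view.downstream_exon
    intron = view.intron
    return RISizeRecord(
        event_key=event_key(view.event),
        upstream_exon_len=up[1] - up[0],
        retained_intron_len=intron[1] - intron[0],
        downstream_exon_len=dn[1] - dn[0],
    )


def ri_intron_exon_sizes(
    events: Iterable[SpliceEvent],
    annotated_introns: Sequence[tuple] = (),
) -> tuple[list[RISizeRecord], list[float], list[float]]:
    """Per-event RI size records plus event means and annotated baselines."""
    records = []
    for ev in events:
        if ev.as_type is not ASType.RI:
            raise ValueError(f"expected RI events, got {ev.as_type}")
        records.append(ri_size_record(RIEventView(ev)))
    event_means = _mean_columns([r.as_tuple() for r in records], 3)
    base_rows = [
        (up[1] - up[0], intron[1] - intron[0], dn[1] - dn[0])
        for _, _, up, intron, dn in annotated_introns
    ]
    baseline_means = _mean_columns(base_rows, 3)
    return records, event_means, baseline_means


# ---------------------------------------------------------------- writers


def _bed_score(fdr: float) -> int:
    if fdr <= 0:
        return 3000
    return min(3000, int(round(-10 * math.log10(fdr))))


def write_unannotated(outdir: str | Path, label: str, summary: AnnotationSummary) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frac = summary.fraction_unannotated
    with open(outdir / f"unannotated_summary_{label}.tsv", "w") as fh:
        fh.write("sign\ttotal\tannotated\tunannotated\tfraction_unannotated\n")
        fh.write(
            f"{label}\t{summary.total}\t{summary.annotated}\t{summary.unannotated}\t"
            f"{'NA' if frac is None else f'{frac:.4f}'}\n"
        )
    with open(outdir / f"unannotated_junctions_{label}.bed", "w") as fh:
        for s in summary.statuses:
            if s.annotated:
                continue
            chrom, strand, a, b = s.skip_junction
            fh.write(
                f"{chrom}\t{a}\t{b}\t{s.gene_symbol}\t{_bed_score(s.fdr)}\t{strand}\n"
            )


def write_number_skipped(
    outdir: str | Path, label: str, hist: dict[str, int], records: list[SkipCountRecord]
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"number_skipped_summary_{label}.tsv", "w") as fh:
        fh.write("bin\tcount\n")
        for b in HISTOGRAM_BINS:
            fh.write(f"{b}\t{hist[b]}\n")
    with open(outdir / f"number_skipped_events_{label}.tsv", "w") as fh:
        fh.write("event_key\tgene\tn_intervening\n")
        for r in records:
            fh.write(f"{r.event_key}\t{r.gene_symbol}\t{r.n_intervening}\n")


def write_sizes(
    outdir: str | Path,
    label: str,
    fields: Sequence[str],
    records: Sequence,
    event_means: Sequence[float],
    baseline_means: Sequence[float],
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(r.event_key, *r.as_tuple()) for r in records],
        columns=["event_key", *fields],
    ).to_csv(outdir / f"sizes_events_{label}.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"field": fields, "event_mean": event_means, "annotated_mean": baseline_means}
    ).to_csv(outdir / f"sizes_summary_{label}.tsv", sep="\t", index=False)
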