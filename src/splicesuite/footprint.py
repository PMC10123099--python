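"""Transcriptome footprint of alternative splicing.

Given a gene-level TPM table (control columns first, then test columns)
and significance-filtered splicing events, computes the fraction of
expressed genes — mean control TPM at or above each requested threshold —
that carry at least one significant event of the requested sign.  This is
the gene-level "how much of the transcriptome moved" summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .rmats_io import Sign, SpliceEvent

logger = logging.getLogger(__name__)


@dataclass
class ExpressionTable:
    """Gene TPMs split into control and test column blocks."""

    genes: list[str]
    control: pd.DataFrame  # rows = genes, columns = control replicates
    test: pd.DataFrame

    def control_mean(self) -> pd.Series:
        return self.control.mean(axis=1)

    def control_min(self) -> pd.Series:
        return self.control.min(axis=1)


@dataclass
class FootprintRow:
    min_tpm: float
    sign: Sign
    expressed_gene_count: int
    as_gene_count: int
    fraction: float | None  # None when no gene passes the threshold


@dataclass
class FootprintSummary:
    rows: list[FootprintRow]
    gene_events: dict[str, list[str]]  # expressed gene -> event keys
    unmatched_genes: list[str]  # event genes absent from the expression table


def read_expression(
    path: str | Path, n_control: int, n_test: int | None = None
) -> ExpressionTable:
    """Read a TPM table: gene IDs in column 1, control then test TPM columns.

    A header line is auto-detected (non-numeric second field on line 1).
    Duplicate gene IDs keep the row with the larger control mean.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if not first.strip():
        raise ValueError(f"{path}: empty expression file")
    fields = first.rstrip("\n").split("\t")
    has_header = False
    if len(fields) > 1:
        try:
            float(fields[1])
        except ValueError:
            has_header = True
    df = pd.read_csv(path, sep="\t", header=0 if has_header else None, dtype={0: str})
    df = df.rename(columns={df.columns[0]: "gene_id"})
    value_cols = list(df.columns[1:])
    if n_test is None:
        n_test = len(value_cols) - n_control
    if n_control < 1 or n_test < 0 or n_control + n_test > len(value_cols):
        raise ValueError(
            f"{path}: {len(value_cols)} TPM columns cannot hold "
            f"{n_control} control + {n_test} test"
        )
    try:
        values = df[value_cols].astype(float)
    except ValueError as exc:
        raise ValueError(f"{path}: non-numeric TPM value ({exc})") from None
    if (values < 0).any().any():
        raise ValueError(f"{path}: negative TPM value")
    df[value_cols] = values
    ctrl_cols = value_cols[:n_control]
    test_cols = value_cols[n_control : n_control + n_test]
    if df["gene_id"].duplicated().any():
        n_dup = int(df["gene_id"].duplicated().sum())
        logger.warning("expression table: %d duplicate gene id(s); keeping max control mean", n_dup)
        df = (
            df.assign(_m=df[ctrl_cols].mean(axis=1))
            .sort_values("_m", ascending=False)
            .drop_duplicates("gene_id", keep="first")
            .sort_index()
            .drop(columns="_m")
        )
    genes = df["gene_id"].tolist()
    ctrl = df[ctrl_cols].set_axis(genes, axis=0)
    test = df[test_cols].set_axis(genes, axis=0)
    return ExpressionTable(genes=genes, control=ctrl, test=test)


def fraction_expressed(
    events: Iterable[SpliceEvent],
    expr: ExpressionTable,
    min_tpms: Sequence[float] = (1, 2, 3, 5),
    sign: Sign = Sign.NEGATIVE,
    *,
    all_replicates: bool = False,
) -> FootprintSummary:
    """Fraction of expressed genes with >=1 significant event of ``sign``.

    ``events`` must already be significance-filtered.  A gene is expressed
    at threshold t when its mean control TPM >= t (or every control column
    >= t with ``all_replicates``).  Event genes missing from the expression
    table are reported in ``unmatched_genes`` and excluded from fractions.
    """
    from .rmats_io import event_key

    if not expr.genes:
        raise ValueError("empty expression table")
    if not min_tpms:
        raise ValueError("min_tpms must be non-empty")

    level = expr.control_min() if all_replicates else expr.control_mean()
    known = set(expr.genes)

    wanted: dict[str, list[str]] = {}
    unmatched: set[str] = set()
    for ev in events:
        if sign is Sign.NEGATIVE and not ev.inc_diff < 0:
            continue
        if sign is Sign.POSITIVE and not ev.inc_diff > 0:
            continue
        if ev.gene_symbol in known:
            wanted.setdefault(ev.gene_symbol, []).append(event_key(ev))
        else:
            unmatched.add(ev.gene_symbol)
    if unmatched:
        logger.warning(
            "%d event gene symbol(s) absent from the expression table", len(unmatched)
        )

    rows = []
    for t in min_tpms:
        expressed = level[level >= t]
        n_expr = int(expressed.shape[0])
        n_as = sum(1 for g in wanted if g in expressed.index)
        frac = (n_as / n_expr) if n_expr else None
        rows.append(
            FootprintRow(
                min_tpm=float(t),
                sign=sign,
                expressed_gene_count=n_expr,
                as_gene_count=n_as,
                fraction=frac,
            )
        )
    return FootprintSummary(rows=rows, gene_events=wanted, unmatched_genes=sorted(unmatched))


def summary_frame(summary: FootprintSummary) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "min_tpm": [r.min_tpm for r in summary.rows],
            "sign": [r.sign.value for r in summary.rows],
            "expressed_genes": [r.expressed_gene_count for r in summary.rows],
            "as_genes": [r.as_gene_count for r in summary.rows],
            "fraction": [r.fraction if r.fraction is not None else float("nan") for r in summary.rows],
        }
    )


def write_footprint(outdir: str | Path, summaries: Sequence[FootprintSummary]) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = pd.concat([summary_frame(s) for s in summaries], ignore_index=True)
    frame.to_csv(outdir / "footprint_summary.tsv", sep="\t", index=False)
    with open(outdir / "footprint_gene_events.tsv", "w") as fh:
        fh.write("sign\tgene\tevent_keys\n")
        for s in summaries:
            sign = s.rows[0].sign.value if s.rows else ""
            for gene, keys in sorted(s.gene_events.items()):
                fh.write(f"{sign}\t{gene}\t{','.join(keys)}\n")
    with open(outdir / "footprint_unmatched_genes.txt", "w") as fh:
        for s in summaries:
            for g in s.unmatched_genes:
                fh.write(g + "\n")
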