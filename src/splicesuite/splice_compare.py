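"""Cross-experiment overlap of significant splicing events.

Each experiment contributes, per AS type, the set of all tested event
keys and the subsets significant at the FDR threshold with positive or
negative inclusion difference.  For every experiment pair the overlap of
significant sets is tested with an exact upper-tail hypergeometric
probability, using the union of all tested events across the two
experiments as the population.  Square p-value and -log10(p) matrices are
written per type and sign, and the -log10 matrix is hierarchically
clustered into a heatmap.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .rmats_io import (
    ASType,
    RmatsFormatError,
    RmatsValidationError,
    SignificanceFilter,
    Sign,
    SpliceEvent,
    event_key,
    filter_significant,
    read_rmats,
)

logger = logging.getLogger(__name__)

P_FLOOR = 1e-300  # p-values are floored here before -log10

_SUFFIX_RE = re.compile(r"^(?P<name>.+)_(?P<type>A3SS|A5SS|MXE|RI|SE)\.MATS\.JCEC\.txt$")


@dataclass
class ExperimentSet:
    """Per-experiment event-key sets for one AS type."""

    name: str
    as_type: ASType
    all_keys: set[str]
    sig_pos: set[str]
    sig_neg: set[str]

    def significant(self, sign: str) -> set[str]:
        if sign == "pos":
            return self.sig_pos
        if sign == "neg":
            return self.sig_neg
        if sign == "total":
            return self.sig_pos | self.sig_neg
        raise ValueError(f"unknown sign {sign!r}")


@dataclass(frozen=True)
class OverlapResult:
    k: int  # overlap of significant sets
    K: int  # |significant(A)|
    n: int  # |significant(B)|
    N: int  # |all_keys(A) ∪ all_keys(B)|
    p: float  # upper-tail hypergeometric P(X >= k)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    Computed as a log-space sum of Σ_{i=k}^{min(K,n)} C(K,i) C(N−K,n−i) / C(N,n)
    for numerical stability at genome-scale set sizes.
    """
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0

    def log_comb(a: int, b: int) -> float:
        return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)

    denom = log_comb(N, n)
    terms = []
    for i in range(k, min(K, n) + 1):
        if n - i > N - K:
            continue
        terms.append(log_comb(K, i) + log_comb(N - K, n - i) - denom)
    if not terms:
        return 0.0
    m = max(terms)
    total = m + math.log(sum(math.exp(t - m) for t in terms))
    return min(1.0, math.exp(total))


def build_experiment_set(
    name: str,
    as_type: ASType,
    events: Sequence[SpliceEvent],
    fdr_threshold: float = 0.0005,
) -> ExperimentSet:
    sig = filter_significant(events, SignificanceFilter(fdr_threshold, Sign.BOTH))
    return ExperimentSet(
        name=name,
        as_type=as_type,
        all_keys={event_key(e) for e in events},
        sig_pos={event_key(e) for e in sig if e.inc_diff > 0},
        sig_neg={event_key(e) for e in sig if e.inc_diff < 0},
    )


def load_experiment_dir(
    directory: str | Path,
    fdr_threshold: float = 0.0005,
    types: Sequence[ASType] = tuple(ASType),
    *,
    lenient: bool = False,
) -> tuple[dict[ASType, list[ExperimentSet]], list[str]]:
    """Load every suffix-conforming JCEC file in a directory.

    Returns the experiment sets grouped by AS type plus a skip report of
    files that failed to parse.  Duplicate experiment names for the same
    type are an error.
    """
    directory = Path(directory)
    wanted = set(types)
    by_type: dict[ASType, list[ExperimentSet]] = {t: [] for t in wanted}
    skipped: list[str] = []
    n_loaded = 0
    for path in sorted(directory.iterdir()):
        m = _SUFFIX_RE.match(path.name)
        if not m:
            continue
        as_type = ASType(m.group("type"))
        if as_type not in wanted:
            continue
        name = m.group("name")
        if any(es.name == name for es in by_type[as_type]):
            raise ValueError(f"duplicate experiment name {name!r} for {as_type.value}")
        try:
            events = read_rmats(path, as_type, lenient=lenient)
        except (RmatsFormatError, RmatsValidationError, OSError) as exc:
            logger.warning("skipping %s: %s", path.name, exc)
            skipped.append(f"{path.name}\t{exc}")
            continue
        by_type[as_type].append(
            build_experiment_set(name, as_type, events, fdr_threshold)
        )
        n_loaded += 1
    if n_loaded == 0:
        raise ValueError(f"no parseable suffix-conforming JCEC files in {directory}")
    return by_type, skipped


def pairwise_compare(
    a: ExperimentSet, b: ExperimentSet, sign: str, population: str = "union"
) -> OverlapResult:
    """Overlap of two experiments' significant sets with its hypergeometric p.

    The population N defaults to the union of all tested events across
    the two files; ``population="intersection"`` restricts it (and the
    significant sets) to events tested in both, for sensitivity analysis.
    """
    if a.as_type is not b.as_type:
        raise ValueError("pairwise comparison requires matching AS types")
    sig_a = a.significant(sign)
    sig_b = b.significant(sign)
    if population == "union":
        pop = a.all_keys | b.all_keys
    elif population == "intersection":
        pop = a.all_keys & b.all_keys
        sig_a = sig_a & pop
        sig_b = sig_b & pop
    else:
        raise ValueError(f"unknown population rule {population!r}")
    k = len(sig_a & sig_b)
    return OverlapResult(
        k=k,
        K=len(sig_a),
        n=len(sig_b),
        N=len(pop),
        p=hypergeom_upper(k, len(sig_a), len(sig_b), len(pop)),
    )


SIGNS = ("pos", "neg", "total")


@dataclass
class CompareMatrices:
    as_type: ASType
    sign: str
    names: list[str]
    p_matrix: pd.DataFrame
    log_matrix: pd.DataFrame  # -log10(p), diagonal masked to 0 for clustering
    results: dict[tuple[str, str], OverlapResult]


def bh_adjust(p_matrix: pd.DataFrame) -> pd.DataFrame:
    """Benjamini-Hochberg adjustment over the off-diagonal upper triangle."""
    from scipy.stats import false_discovery_control

    p = p_matrix.to_numpy().copy()
    iu = np.triu_indices_from(p, k=1)
    if iu[0].size:
        adjusted = false_discovery_control(p[iu], method="bh")
        p[iu] = adjusted
        p[(iu[1], iu[0])] = adjusted
    return pd.DataFrame(p, index=p_matrix.index, columns=p_matrix.columns)


def compare_experiments(
    experiments: Sequence[ExperimentSet], sign: str, population: str = "union"
) -> CompareMatrices:
    if len(experiments) < 2:
        raise ValueError("at least two experiments are required")
    names = [e.name for e in experiments]
    n = len(names)
    p = np.ones((n, n))
    results: dict[tuple[str, str], OverlapResult] = {}
    for i in range(n):
        for j in range(i, n):
            if i == j:
                # self-comparison: minimal achievable tail for this set
                e = experiments[i]
                sig = e.significant(sign)
                p[i, i] = hypergeom_upper(
                    len(sig), len(sig), len(sig), len(e.all_keys)
                )
                continue
            res = pairwise_compare(experiments[i], experiments[j], sign, population)
            results[(names[i], names[j])] = res
            p[i, j] = p[j, i] = res.p
    p_df = pd.DataFrame(p, index=names, columns=names)
    log_p = -np.log10(np.maximum(p, P_FLOOR))
    np.fill_diagonal(log_p, 0.0)  # mask self-comparisons out of clustering
    return CompareMatrices(
        as_type=experiments[0].as_type,
        sign=sign,
        names=names,
        p_matrix=p_df,
        log_matrix=pd.DataFrame(log_p, index=names, columns=names),
        results=results,
    )


def cluster_order(log_matrix: pd.DataFrame) -> list[str]:
    """Leaf order of average-linkage Euclidean clustering of -log10(p) rows."""
    from scipy.cluster.hierarchy import average, leaves_list

    if log_matrix.shape[0] < 2:
        return list(log_matrix.index)
    link = average(_condensed(log_matrix))
    return [log_matrix.index[i] for i in leaves_list(link)]


def cluster_labels(log_matrix: pd.DataFrame, n_clusters: int) -> dict[str, int]:
    """Flat cluster membership from the same linkage used for the heatmap."""
    from scipy.cluster.hierarchy import average, fcluster

    link = average(_condensed(log_matrix))
    labels = fcluster(link, t=n_clusters, criterion="maxclust")
    return dict(zip(log_matrix.index, labels.tolist()))


def _condensed(log_matrix: pd.DataFrame) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(log_matrix.to_numpy(), metric="euclidean")


def write_compare_outputs(
    outdir: str | Path,
    matrices: CompareMatrices,
    *,
    heatmap: bool = True,
    bh: bool = False,
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tag = f"{matrices.as_type.value}_{matrices.sign}"
    matrices.p_matrix.to_csv(outdir / f"pvalue_matrix_{tag}.tsv", sep="\t")
    if bh:
        bh_adjust(matrices.p_matrix).to_csv(
            outdir / f"pvalue_matrix_bh_{tag}.tsv", sep="\t"
        )
    matrices.log_matrix.to_csv(outdir / f"neglog10_matrix_{tag}.tsv", sep="\t")
    with open(outdir / f"overlap_summary_{tag}.tsv", "w") as fh:
        fh.write("exp_a\texp_b\tk\tK\tn\tN\tp\n")
        for (a, b), r in matrices.results.items():
            fh.write(f"{a}\t{b}\t{r.k}\t{r.K}\t{r.n}\t{r.N}\t{r.p:.6g}\n")
    with open(outdir / f"clustering_metadata_{tag}.txt", "w") as fh:
        fh.write(
            "clustering: average linkage, Euclidean distance on -log10(p) rows, "
            "diagonal masked\n"
        )
    if heatmap:
        _write_heatmap(outdir / f"heatmap_{tag}.png", matrices)


def _write_heatmap(path: Path, matrices: CompareMatrices) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = cluster_order(matrices.log_matrix)
    data = matrices.log_matrix.loc[order, order]
    fig, ax = plt.subplots(figsize=(max(4, 0.4 * len(order)),) * 2)
    im = ax.imshow(data.to_numpy(), cmap="viridis")
    ax.set_xticks(range(len(order)), order, rotation=90, fontsize=6)
    ax.set_yticks(range(len(order)), order, fontsize=6)
    fig.colorbar(im, ax=ax, label="-log10(p)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_summary(by_type: dict[ASType, list[ExperimentSet]]) -> pd.DataFrame:
    """Per-experiment counts of positive/negative/total significant events."""
    rows = []
    for as_type, experiments in by_type.items():
        for e in experiments:
            rows.append(
                {
                    "experiment": e.name,
                    "as_type": as_type.value,
                    "sig_positive": len(e.sig_pos),
                    "sig_negative": len(e.sig_neg),
                    "sig_total": len(e.sig_pos | e.sig_neg),
                    "tested": len(e.all_keys),
                }
            )
    return pd.DataFrame(rows)


def compare_all(
    directory: str | Path,
    outdir: str | Path,
    fdr_threshold: float = 0.0005,
    types: Sequence[ASType] = tuple(ASType),
    *,
    emit_event_lists: bool = False,
    heatmap: bool = True,
    bh: bool = False,
    population: str = "union",
) -> dict[tuple[ASType, str], CompareMatrices]:
    """Full pairwise comparison over a directory of JCEC files."""
    by_type, skipped = load_experiment_dir(directory, fdr_threshold, types)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_summary(by_type).to_csv(outdir / "experiment_summary.tsv", sep="\t", index=False)
    if skipped:
        (outdir / "skipped_files.tsv").write_text("\n".join(skipped) + "\n")
    out: dict[tuple[ASType, str], CompareMatrices] = {}
    for as_type, experiments in by_type.items():
        if len(experiments) < 2:
            continue
        for sign in SIGNS:
            matrices = compare_experiments(experiments, sign, population)
            write_compare_outputs(outdir, matrices, heatmap=heatmap, bh=bh)
            out[(as_type, sign)] = matrices
            if emit_event_lists:
                _write_event_lists(outdir, experiments, as_type, sign)
    if not out:
        raise ValueError("no AS type had at least two experiments to compare")
    return out


def _write_event_lists(
    outdir: Path, experiments: Sequence[ExperimentSet], as_type: ASType, sign: str
) -> None:
    n_pairs = len(experiments) * (len(experiments) - 1) // 2
    if n_pairs > 100:
        logger.warning(
            "emitting common-event lists for %d pairs; this creates many files",
            n_pairs,
        )
    list_dir = outdir / f"common_events_{as_type.value}_{sign}"
    list_dir.mkdir(exist_ok=True)
    for i, a in enumerate(experiments):
        for b in experiments[i + 1 :]:
            common = sorted(a.significant(sign) & b.significant(sign))
            path = list_dir / f"{a.name}__{b.name}.txt"
            path.write_text("\n".join(common) + ("\n" if common else ""))
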