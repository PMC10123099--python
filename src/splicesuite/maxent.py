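"""Maximum-entropy splice-site strength scoring.

Scores are log2 likelihood ratios (bits) of a candidate splice-site
sequence under a splice-site model versus a background model:

* donor (5') sites are 9-mers: 3 exonic bases, then the intron's first 6
  bases.  Intron positions +1/+2 (the near-invariant GT) are scored by a
  consensus frequency ratio; the remaining 7 positions by a joint
  probability table.
* acceptor (3') sites are 23-mers: the intron's last 20 bases then 3
  exonic bases.  Intron positions -2/-1 (the near-invariant AG, 23-mer
  positions 19/20) are scored by consensus frequency ratios; the
  remaining 21 bases by a product of five overlapping 7-mer sub-tables
  divided by four lower-order sub-tables that correct the double counting:

      numerator   windows [0:7) [7:14) [14:21) [4:11) [11:18)
      denominator windows [4:7) [7:11) [11:14) [14:18)

This is the decomposition used by the canonical maximum-entropy splice
site scorer; tables trained on real aligned splice sites can be dropped
into a directory and loaded with :func:`load_models`.  The bundled
default model (:func:`default_models`) is SYNTHETIC: it is the maximum-
entropy distribution subject to first-order (per-position) base frequency
constraints, built from representative mammalian splice-site frequencies
embedded below.  Its scores rank sites sensibly (consensus-like > weak)
but are not numerically comparable to scores from trained tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from statistics import mean
from typing import Iterable, Sequence

import numpy as np

from .annotation import GenomeSequence
from .rmats_io import ASType, RIEventView, SEEventView, SpliceEvent, event_key

DONOR_LEN = 9
ACCEPTOR_LEN = 23
# 0-based positions inside the 9-mer / 23-mer scored by consensus ratios
DONOR_CONS_POS = (3, 4)  # intron +1, +2 (GT)
ACCEPTOR_CONS_POS = (18, 19)  # intron -2, -1 (AG)
DONOR_VAR_POS = (0, 1, 2, 5, 6, 7, 8)

ACCEPTOR_NUM_WINDOWS = ((0, 7), (7, 14), (14, 21), (4, 11), (11, 18))
ACCEPTOR_DEN_WINDOWS = ((4, 7), (7, 11), (11, 14), (14, 18))

_BASES = "ACGT"
_BASE_IDX = {b: i for i, b in enumerate(_BASES)}


class ScoreError(ValueError):
    """Sequence cannot be scored (wrong length or non-ACGT base)."""


def _kmer_index(seq: str) -> int:
    """Lexicographic index of a k-mer over A<C<G<T, first base most significant."""
    idx = 0
    for b in seq:
        try:
            idx = idx * 4 + _BASE_IDX[b]
        except KeyError:
            raise ScoreError(f"non-ACGT base {b!r} in {seq!r}") from None
    return idx


@dataclass
class SpliceSiteModels:
    """Loaded donor/acceptor probability-ratio tables.

    Tables store model/background probability ratios, one entry per k-mer
    in lexicographic order.  ``donor_consensus`` / ``acceptor_consensus``
    map each consensus position to a 4-vector of model/background
    frequency ratios (indexed A, C, G, T).
    """

    donor_table: np.ndarray  # 4^7 ratios over the variable donor positions
    donor_consensus: dict[int, np.ndarray]
    acceptor_tables: list[np.ndarray]  # 9 windows, numerator then denominator
    acceptor_consensus: dict[int, np.ndarray]
    synthetic: bool = False

    def __post_init__(self) -> None:
        if self.donor_table.shape != (4 ** len(DONOR_VAR_POS),):
            raise ValueError("donor table must have 4^7 entries")
        windows = ACCEPTOR_NUM_WINDOWS + ACCEPTOR_DEN_WINDOWS
        if len(self.acceptor_tables) != len(windows):
            raise ValueError("acceptor model requires 9 sub-tables")
        for tab, (a, b) in zip(self.acceptor_tables, windows):
            if tab.shape != (4 ** (b - a),):
                raise ValueError(f"acceptor sub-table for window [{a},{b}) has wrong size")
        for tab in [self.donor_table, *self.acceptor_tables]:
            if not np.all(tab > 0):
                raise ValueError("probability ratios must be positive")


def score_donor(seq: str, models: SpliceSiteModels) -> float:
    """Score a 9-mer donor site in bits."""
    seq = seq.upper()
    if len(seq) != DONOR_LEN:
        raise ScoreError(f"donor sites are {DONOR_LEN}-mers, got length {len(seq)}")
    ratio = 1.0
    for pos in DONOR_CONS_POS:
        ratio *= models.donor_consensus[pos][_kmer_index(seq[pos])]
    ratio *= models.donor_table[_kmer_index("".join(seq[p] for p in DONOR_VAR_POS))]
    return math.log2(ratio)


def score_acceptor(seq: str, models: SpliceSiteModels) -> float:
    """Score a 23-mer acceptor site in bits."""
    seq = seq.upper()
    if len(seq) != ACCEPTOR_LEN:
        raise ScoreError(f"acceptor sites are {ACCEPTOR_LEN}-mers, got length {len(seq)}")
    log_ratio = 0.0
    for pos in ACCEPTOR_CONS_POS:
        log_ratio += math.log2(models.acceptor_consensus[pos][_kmer_index(seq[pos])])
    rest = "".join(b for i, b in enumerate(seq) if i not in ACCEPTOR_CONS_POS)
    for tab, (a, b) in zip(models.acceptor_tables, ACCEPTOR_NUM_WINDOWS):
        log_ratio += math.log2(tab[_kmer_index(rest[a:b])])
    for tab, (a, b) in zip(
        models.acceptor_tables[len(ACCEPTOR_NUM_WINDOWS) :], ACCEPTOR_DEN_WINDOWS
    ):
        log_ratio -= math.log2(tab[_kmer_index(rest[a:b])])
    return log_ratio


# ------------------------------------------------------- synthetic model

# Representative per-position base frequencies (A, C, G, T) for mammalian
# splice sites; SYNTHETIC stand-in for trained tables (see module docstring).
# Donor 9-mer: exon[-3..-1] then intron[+1..+6]; consensus CAG|GTAAGT.
_DONOR_FREQS = np.array(
    [
        [0.33, 0.37, 0.18, 0.12],  # exon -3 (C/A rich)
        [0.60, 0.13, 0.14, 0.13],  # exon -2 (A)
        [0.09, 0.04, 0.79, 0.08],  # exon -1 (G)
        [0.004, 0.004, 0.988, 0.004],  # intron +1 (G, consensus position)
        [0.004, 0.015, 0.004, 0.977],  # intron +2 (T, consensus position)
        [0.595, 0.030, 0.280, 0.095],  # intron +3 (A)
        [0.710, 0.075, 0.120, 0.095],  # intron +4 (A)
        [0.070, 0.055, 0.815, 0.060],  # intron +5 (G)
        [0.160, 0.150, 0.190, 0.500],  # intron +6 (T)
    ]
)

# Acceptor 23-mer: intron[-20..-1] then exon[+1..+3]; polypyrimidine tract,
# branch-distal C enrichment, invariant AG at intron -2/-1.
_ACCEPTOR_FREQS = np.array(
    [[0.10, 0.31, 0.14, 0.45]] * 14  # intron -20..-7: pyrimidine tract
    + [
        [0.065, 0.350, 0.080, 0.505],  # -6
        [0.080, 0.370, 0.075, 0.475],  # -5
        [0.230, 0.300, 0.215, 0.255],  # -4
        [0.050, 0.650, 0.015, 0.285],  # -3 (C)
        [0.970, 0.010, 0.010, 0.010],  # -2 (A, consensus position)
        [0.010, 0.010, 0.970, 0.010],  # -1 (G, consensus position)
        [0.245, 0.155, 0.500, 0.100],  # exon +1 (G)
        [0.300, 0.210, 0.235, 0.255],  # exon +2
        [0.240, 0.265, 0.250, 0.245],  # exon +3
    ]
)

_BACKGROUND = np.array([0.25, 0.25, 0.25, 0.25])


def _independence_table(freq_rows: np.ndarray) -> np.ndarray:
    """Joint ratio table that factorizes over positions (first-order maxent)."""
    table = np.ones(1)
    for row in freq_rows:
        table = np.kron(table, row / _BACKGROUND)
    return table


def default_models() -> SpliceSiteModels:
    """The bundled synthetic first-order maximum-entropy model."""
    donor_var = _DONOR_FREQS[list(DONOR_VAR_POS)]
    rest_freqs = np.delete(_ACCEPTOR_FREQS, ACCEPTOR_CONS_POS, axis=0)
    acceptor_tables = [
        _independence_table(rest_freqs[a:b])
        for a, b in ACCEPTOR_NUM_WINDOWS + ACCEPTOR_DEN_WINDOWS
    ]
    return SpliceSiteModels(
        donor_table=_independence_table(donor_var),
        donor_consensus={
            pos: _DONOR_FREQS[pos] / _BACKGROUND for pos in DONOR_CONS_POS
        },
        acceptor_tables=acceptor_tables,
        acceptor_consensus={
            pos: _ACCEPTOR_FREQS[pos] / _BACKGROUND for pos in ACCEPTOR_CONS_POS
        },
        synthetic=True,
    )


# ------------------------------------------------------- table file I/O

_DONOR_FILE = "donor_me.txt"
_CONS_FILE = "consensus_ratios.tsv"
_ACCEPTOR_FILES = [f"acceptor_me{i}.txt" for i in range(1, 10)]


def save_models(models: SpliceSiteModels, directory: str | Path) -> None:
    """Write model tables: one ratio per line, k-mers in lexicographic order."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    np.savetxt(directory / _DONOR_FILE, models.donor_table, fmt="%.10g")
    for fname, tab in zip(_ACCEPTOR_FILES, models.acceptor_tables):
        np.savetxt(directory / fname, tab, fmt="%.10g")
    with open(directory / _CONS_FILE, "w") as fh:
        fh.write("site\tposition\tA\tC\tG\tT\n")
        for pos in DONOR_CONS_POS:
            vals = "\t".join(f"{v:.10g}" for v in models.donor_consensus[pos])
            fh.write(f"donor\t{pos}\t{vals}\n")
        for pos in ACCEPTOR_CONS_POS:
            vals = "\t".join(f"{v:.10g}" for v in models.acceptor_consensus[pos])
            fh.write(f"acceptor\t{pos}\t{vals}\n")


class ModelLoadError(ValueError):
    pass


def load_models(directory: str | Path) -> SpliceSiteModels:
    """Load model tables written by :func:`save_models` (or trained tables
    converted to the same dialect)."""
    directory = Path(directory)
    for fname in [_DONOR_FILE, _CONS_FILE, *_ACCEPTOR_FILES]:
        if not (directory / fname).exists():
            raise ModelLoadError(f"missing model table {fname} in {directory}")

    def _read(fname: str, expected: int) -> np.ndarray:
        arr = np.loadtxt(directory / fname, dtype=float, ndmin=1)
        if arr.shape != (expected,):
            raise ModelLoadError(
                f"{fname}: expected {expected} entries, found {arr.shape[0]}"
            )
        if not np.all(arr > 0):
            raise ModelLoadError(f"{fname}: non-positive probability ratio")
        return arr

    donor = _read(_DONOR_FILE, 4 ** len(DONOR_VAR_POS))
    acceptor = [
        _read(fname, 4 ** (b - a))
        for fname, (a, b) in zip(
            _ACCEPTOR_FILES, ACCEPTOR_NUM_WINDOWS + ACCEPTOR_DEN_WINDOWS
        )
    ]
    donor_cons: dict[int, np.ndarray] = {}
    acc_cons: dict[int, np.ndarray] = {}
    with open(directory / _CONS_FILE) as fh:
        next(fh)
        for line in fh:
            site, pos, *vals = line.split("\t")
            target = donor_cons if site == "donor" else acc_cons
            target[int(pos)] = np.array([float(v) for v in vals])
    if set(donor_cons) != set(DONOR_CONS_POS) or set(acc_cons) != set(ACCEPTOR_CONS_POS):
        raise ModelLoadError(f"{_CONS_FILE}: missing consensus positions")
    return SpliceSiteModels(
        donor_table=donor,
        donor_consensus=donor_cons,
        acceptor_tables=acceptor,
        acceptor_consensus=acc_cons,
    )


# --------------------------------------------------- event site scoring

SE_ROLES = ("upstream_donor", "skipped_acceptor", "skipped_donor", "downstream_acceptor")
RI_ROLES = ("ri_donor", "ri_acceptor")


@dataclass(frozen=True)
class SiteScoreRecord:
    event_key: str
    site_role: str
    sequence: str
    score: float | None  # None when flagged (non-ACGT or off-contig)
    inc_diff: float = 0.0


def _donor_window(
    genome: GenomeSequence, chrom: str, strand: str, exon: tuple[int, int]
) -> str:
    """9-mer at the transcript-3' boundary of ``exon`` (3 exonic + 6 intronic)."""
    if strand == "+":
        return genome.fetch(chrom, exon[1] - 3, exon[1] + 6, "+")
    return genome.fetch(chrom, exon[0] - 6, exon[0] + 3, "-")


def _acceptor_window(
    genome: GenomeSequence, chrom: str, strand: str, exon: tuple[int, int]
) -> str:
    """23-mer at the transcript-5' boundary of ``exon`` (20 intronic + 3 exonic)."""
    if strand == "+":
        return genome.fetch(chrom, exon[0] - 20, exon[0] + 3, "+")
    return genome.fetch(chrom, exon[1] - 3, exon[1] + 20, "-")


def _score_site(
    genome: GenomeSequence,
    models: SpliceSiteModels,
    chrom: str,
    strand: str,
    exon: tuple[int, int],
    donor: bool,
) -> tuple[str, float | None]:
    try:
        if donor:
            seq = _donor_window(genome, chrom, strand, exon)
            return seq, score_donor(seq, models)
        seq = _acceptor_window(genome, chrom, strand, exon)
        return seq, score_acceptor(seq, models)
    except (ScoreError, ValueError):
        return "", None


def _se_site_specs(view: SEEventView) -> list[tuple[str, tuple[int, int], bool]]:
    skipped = (view.exon_start, view.exon_end)
    return [
        ("upstream_donor", view.upstream_exon, True),
        ("skipped_acceptor", skipped, False),
        ("skipped_donor", skipped, True),
        ("downstream_acceptor", view.downstream_exon, False),
    ]


def score_event_sites(
    events: Iterable[SpliceEvent],
    genome: GenomeSequence,
    models: SpliceSiteModels,
    as_type: ASType,
) -> list[SiteScoreRecord]:
    """Per-event splice-site scores (4 sites per SE event, 2 per RI event)."""
    records: list[SiteScoreRecord] = []
    for ev in events:
        key = event_key(ev)
        if as_type is ASType.SE:
            view = SEEventView(ev)
            specs = _se_site_specs(view)
        elif as_type is ASType.RI:
            ri = RIEventView(ev)
            specs = [
                ("ri_donor", ri.upstream_exon, True),
                ("ri_acceptor", ri.downstream_exon, False),
            ]
        else:
            raise ValueError(f"splice-site scoring supports SE and RI, not {as_type}")
        for role, exon, is_donor in specs:
            seq, score = _score_site(genome, models, ev.chrom, ev.strand, exon, is_donor)
            records.append(
                SiteScoreRecord(
                    event_key=key,
                    site_role=role,
                    sequence=seq,
                    score=score,
                    inc_diff=ev.inc_diff,
                )
            )
    return records


def mean_scores_by_role(records: Iterable[SiteScoreRecord]) -> dict[str, float]:
    """Mean score per site role; flagged records are excluded."""
    buckets: dict[str, list[float]] = {}
    for r in records:
        if r.score is not None:
            buckets.setdefault(r.site_role, []).append(r.score)
    return {role: mean(vals) for role, vals in buckets.items() if vals}


def score_annotated_baseline(
    configs: Sequence[tuple],
    genome: GenomeSequence,
    models: SpliceSiteModels,
    as_type: ASType,
) -> dict[str, float]:
    """Reference means over annotated skipping/retention configurations.

    ``configs`` comes from ``enumerate_annotated_se_triples`` (SE) or
    ``enumerate_annotated_introns`` (RI).
    """
    buckets: dict[str, list[float]] = {}
    for rec in configs:
        chrom, strand = rec[0], rec[1]
        if as_type is ASType.SE:
            up, mid, dn = rec[2], rec[3], rec[4]
            specs = [
                ("upstream_donor", up, True),
                ("skipped_acceptor", mid, False),
                ("skipped_donor", mid, True),
                ("downstream_acceptor", dn, False),
            ]
        else:
            up, _intron, dn = rec[2], rec[3], rec[4]
            specs = [("ri_donor", up, True), ("ri_acceptor", dn, False)]
        for role, exon, is_donor in specs:
            _seq, score = _score_site(genome, models, chrom, strand, exon, is_donor)
            if score is not None:
                buckets.setdefault(role, []).append(score)
    return {role: mean(vals) for role, vals in buckets.items() if vals}


def score_ratio_table(
    neg_means: dict[str, float], pos_means: dict[str, float]
) -> dict[str, float]:
    """Ratio of increased-event to decreased-event mean scores per role."""
    out = {}
    for role, neg in neg_means.items():
        pos = pos_means.get(role)
        if pos:
            out[role] = neg / pos
    return out


def write_site_scores(
    outdir: str | Path,
    label: str,
    records: Sequence[SiteScoreRecord],
    means: dict[str, float],
    baseline: dict[str, float],
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"site_scores_{label}.tsv", "w") as fh:
        fh.write("event_key\tsite_role\tsequence\tscore_bits\tflagged\n")
        for r in records:
            score = "NA" if r.score is None else f"{r.score:.2f}"
            fh.write(
                f"{r.event_key}\t{r.site_role}\t{r.sequence}\t{score}\t"
                f"{int(r.score is None)}\n"
            )
    with open(outdir / f"site_score_means_{label}.tsv", "w") as fh:
        fh.write("site_role\tevent_mean_bits\tannotated_mean_bits\n")
        for role in sorted(set(means) | set(baseline)):
            m = means.get(role)
            b = baseline.get(role)
            fh.write(
                f"{role}\t{'NA' if m is None else f'{m:.2f}'}\t"
                f"{'NA' if b is None else f'{b:.2f}'}\n"
            )
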