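"""Maximum-entropy splice-site scoring: parity, consensus, orientation."""

import math
from statistics import mean, median

import numpy as np
import pytest

from splicesuite.maxent import (
    ACCEPTOR_CONS_POS,
    ACCEPTOR_DEN_WINDOWS,
    ACCEPTOR_NUM_WINDOWS,
    DONOR_CONS_POS,
    DONOR_VAR_POS,
    ModelLoadError,
    ScoreError,
    default_models,
    load_models,
    mean_scores_by_role,
    save_models,
    score_acceptor,
    score_donor,
    score_event_sites,
)
from splicesuite.rmats_io import ASType, SpliceEvent

BASES = "ACGT"


@pytest.fixture(scope="module")
def models():
    return default_models()


@pytest.fixture(scope="module")
def table_dir(tmp_path_factory, models):
    out = tmp_path_factory.mktemp("metables")
    save_models(models, out)
    return out


def _naive_score_from_files(table_dir, seq):
    """Independent re-scorer: reads the table files directly and applies the
    decomposition with plain Python lookups (no shared code path)."""

    def kidx(kmer):
        return int("".join(str(BASES.index(b)) for b in kmer), 4)

    cons = {}
    with open(table_dir / "consensus_ratios.tsv") as fh:
        next(fh)
        for line in fh:
            site, pos, *vals = line.split("\t")
            cons[(site, int(pos))] = [float(v) for v in vals]
    if len(seq) == 9:
        table = [float(x) for x in (table_dir / "donor_me.txt").read_text().split()]
        ratio = cons[("donor", 3)][BASES.index(seq[3])]
        ratio *= cons[("donor", 4)][BASES.index(seq[4])]
        ratio *= table[kidx("".join(seq[p] for p in DONOR_VAR_POS))]
        return math.log2(ratio)
    ratio = cons[("acceptor", 18)][BASES.index(seq[18])]
    ratio *= cons[("acceptor", 19)][BASES.index(seq[19])]
    rest = seq[:18] + seq[20:]
    for i, (a, b) in enumerate(ACCEPTOR_NUM_WINDOWS, start=1):
        table = [float(x) for x in (table_dir / f"acceptor_me{i}.txt").read_text().split()]
        ratio *= table[kidx(rest[a:b])]
    for i, (a, b) in enumerate(ACCEPTOR_DEN_WINDOWS, start=6):
        table = [float(x) for x in (table_dir / f"acceptor_me{i}.txt").read_text().split()]
        ratio /= table[kidx(rest[a:b])]
    return math.log2(ratio)


class TestScoring:
    def test_parity_with_table_files_on_random_panel(self, models, table_dir):
        """Package scorer vs an independent file-reading oracle, 1000 seqs."""
        rng = np.random.default_rng(1234)
        for _ in range(500):
            donor = "".join(rng.choice(list(BASES), 9))
            acceptor = "".join(rng.choice(list(BASES), 23))
            assert score_donor(donor, models) == pytest.approx(
                _naive_score_from_files(table_dir, donor), abs=1e-3
            )
            assert score_acceptor(acceptor, models) == pytest.approx(
                _naive_score_from_files(table_dir, acceptor), abs=1e-3
            )

    def test_consensus_donor_maximal_over_exhaustive_enumeration(self, models):
        """CAG|GTAAGT beats every other GT-core 9-mer (4^7 enumeration)."""
        import itertools

        consensus = "CAGGTAAGT"
        best_score = score_donor(consensus, models)
        for combo in itertools.product(BASES, repeat=7):
            v = "".join(combo)
            seq = v[:3] + "GT" + v[3:]
            if seq == consensus:
                continue
            assert score_donor(seq, models) < best_score

    def test_scoring_is_deterministic(self, models):
        seq = "CAGGTAAGT"
        assert score_donor(seq, models) == score_donor(seq, models)
        acc = "TCTTTCTTTTCTTTCTCCAGGAC"
        assert abs(score_acceptor(acc, models) - score_acceptor(acc, models)) < 1e-12

    def test_non_ag_acceptor_scores_low_without_crashing(self, models):
        canonical = "TCTTTCTTTTCTTTCTCCAGGAC"
        broken = canonical[:18] + "CC" + canonical[20:]
        assert score_acceptor(broken, models) < score_acceptor(canonical, models) - 5

    def test_polypyrimidine_acceptor_beats_shuffles(self, models):
        canonical = "TCTTTCTTTTCTTTCTCCAGGAC"
        rng = np.random.default_rng(99)
        shuffled_scores = []
        for _ in range(100):
            chars = list(canonical)
            rng.shuffle(chars)
            shuffled_scores.append(score_acceptor("".join(chars), models))
        assert score_acceptor(canonical, models) > median(shuffled_scores)

    @pytest.mark.parametrize("seq,fn", [
        ("ACGT", score_donor),
        ("N" * 9, score_donor),
        ("ACGT" * 5, score_acceptor),
        ("N" * 23, score_acceptor),
    ])
    def test_bad_sequences_raise(self, models, seq, fn):
        with pytest.raises(ScoreError):
            fn(seq, models)


class TestModelIO:
    def test_load_round_trip(self, models, table_dir):
        loaded = load_models(table_dir)
        assert np.allclose(loaded.donor_table, models.donor_table, rtol=1e-8)
        for a, b in zip(loaded.acceptor_tables, models.acceptor_tables):
            assert np.allclose(a, b, rtol=1e-8)

    def test_missing_table_file_named_in_error(self, tmp_path):
        with pytest.raises(ModelLoadError, match="donor_me.txt"):
            load_models(tmp_path)

    def test_truncated_table_rejected(self, table_dir, tmp_path):
        import shutil

        broken = tmp_path / "broken"
        shutil.copytree(table_dir, broken)
        (broken / "donor_me.txt").write_text("1.0\n2.0\n")
        with pytest.raises(ModelLoadError, match="expected"):
            load_models(broken)


class TestEventScoring:
    def test_strand_mirrored_events_score_identically(self, models, tmp_path):
        # same physical site sequence embedded on both strands
        from splicesuite.annotation import GenomeSequence, revcomp

        rng = np.random.default_rng(5)
        upstream = "".join(rng.choice(list(BASES), 200))
        insert = (
            upstream[:100]
            + "CAG" + "GTAAGT"  # donor at exon end 103
            + "".join(rng.choice(list(BASES), 200))
        )
        plus = insert + "N"
        minus = revcomp(insert) + "N"
        fa = tmp_path / "twin.fa"
        fa.write_text(f">p\n{plus}\n>m\n{minus}\n")
        genome = GenomeSequence(fa)
        from splicesuite.maxent import _donor_window

        w_plus = _donor_window(genome, "p", "+", (0, 103))
        w_minus = _donor_window(genome, "m", "-", (len(insert) - 103, len(insert)))
        assert w_plus == w_minus == "CAGGTAAGT"

    def test_planted_strong_sites_outscore_weak_sites(
        self, se_events, genome, models, truth
    ):
        records = score_event_sites(se_events, genome, models, ASType.SE)
        by_key = {}
        for r in records:
            if r.score is not None:
                by_key.setdefault(r.event_key, []).append(r.score)
        strong = [mean(by_key[k]) for k in truth["maxent_groups"]["strong"] if k in by_key]
        weak = [mean(by_key[k]) for k in truth["maxent_groups"]["weak"] if k in by_key]
        assert strong and weak
        assert mean(strong) > mean(weak)

    def test_se_event_yields_four_roles_ri_two(self, se_events, ri_events, genome, models):
        se_records = score_event_sites(se_events[:1], genome, models, ASType.SE)
        assert [r.site_role for r in se_records] == [
            "upstream_donor", "skipped_acceptor", "skipped_donor", "downstream_acceptor",
        ]
        ri_records = score_event_sites(ri_events[:1], genome, models, ASType.RI)
        assert [r.site_role for r in ri_records] == ["ri_donor", "ri_acceptor"]

    def test_off_contig_site_flagged_and_excluded_from_means(self, models, tmp_path):
        from splicesuite.annotation import GenomeSequence

        fa = tmp_path / "tiny.fa"
        fa.write_text(">c\n" + "ACGT" * 10 + "\n")
        genome = GenomeSequence(fa)
        ev = SpliceEvent(ASType.SE, "G", "c", "+", (10, 20, 2, 6, 30, 38), 1e-9, -0.3)
        records = score_event_sites([ev], genome, models, ASType.SE)
        flagged = [r for r in records if r.score is None]
        assert flagged  # acceptor windows run off the 40-nt contig
        assert all(r.site_role not in mean_scores_by_role(records)
                   or r.score is not None for r in flagged)
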