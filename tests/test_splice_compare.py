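"""Hypergeometric overlap testing and cross-experiment comparison."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from splicesuite.rmats_io import ASType
from splicesuite.splice_compare import (
    cluster_labels,
    compare_all,
    compare_experiments,
    hypergeom_upper,
    load_experiment_dir,
    pairwise_compare,
)


def brute_upper_tail(k, K, n, N):
    """Exact enumeration oracle with rational arithmetic."""
    total = Fraction(0)
    for i in range(k, min(K, n) + 1):
        if n - i <= N - K:
            total += Fraction(comb(K, i) * comb(N - K, n - i), comb(N, n))
    return float(total)


class TestHypergeomUpper:
    @pytest.mark.parametrize("k,K,n,N,expected", [
        (4, 5, 4, 10, 5 / 210),
        (2, 3, 3, 6, 0.5),
        (0, 5, 5, 10, 1.0),
    ])
    def test_hand_computed_tails(self, k, K, n, N, expected):
        assert hypergeom_upper(k, K, n, N) == pytest.approx(expected, abs=1e-12)

    def test_monotone_non_increasing_in_k(self):
        values = [hypergeom_upper(k, 30, 40, 100) for k in range(0, 31)]
        assert all(a >= b for a, b in zip(values, values[1:]))

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper(5, 4, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_upper(0, 11, 4, 10)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_matches_scipy_survival_function(self, data):
        N = data.draw(st.integers(1, 500))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, K + n - N), min(K, n)))
        from scipy.stats import hypergeom

        assert hypergeom_upper(k, K, n, N) == pytest.approx(
            float(hypergeom.sf(k - 1, N, K, n)), rel=1e-9, abs=1e-12
        )


class TestPairwise:
    def test_planted_overlaps_recovered(self, fixture_dir, compare_truth):
        by_type, skipped = load_experiment_dir(fixture_dir / "compare")
        assert not skipped
        exps = {e.name: e for e in by_type[ASType.SE]}
        for pair, expect in compare_truth["pairs"].items():
            a, b = pair.split("|")
            res = pairwise_compare(exps[a], exps[b], "total")
            assert (res.k, res.K, res.n, res.N) == (
                expect["k_total"], expect["K"], expect["n"], expect["N"],
            )
            assert res.p == pytest.approx(
                brute_upper_tail(res.k, res.K, res.n, res.N), rel=1e-9
            )

    def test_symmetry_swaps_set_sizes_only(self, fixture_dir):
        by_type, _ = load_experiment_dir(fixture_dir / "compare")
        a, b = by_type[ASType.SE][:2]
        ab = pairwise_compare(a, b, "neg")
        ba = pairwise_compare(b, a, "neg")
        assert (ab.k, ab.N) == (ba.k, ba.N)
        assert ab.p == pytest.approx(ba.p, rel=1e-9)
        assert (ab.K, ab.n) == (ba.n, ba.K)

    def test_disjoint_sets_give_p_one(self, fixture_dir):
        by_type, _ = load_experiment_dir(fixture_dir / "compare")
        exps = {e.name: e for e in by_type[ASType.SE]}
        res = pairwise_compare(exps["expA1"], exps["expB1"], "total")
        # cluster cores are disjoint; jitter may add a few common spares
        assert res.p == pytest.approx(
            brute_upper_tail(res.k, res.K, res.n, res.N), rel=1e-9
        )

    def test_sign_sets_partition_total(self, fixture_dir):
        by_type, _ = load_experiment_dir(fixture_dir / "compare")
        for e in by_type[ASType.SE]:
            assert e.sig_pos.isdisjoint(e.sig_neg)
            assert e.significant("total") == e.sig_pos | e.sig_neg
            assert e.significant("total") <= e.all_keys


class TestCompareAll:
    def test_matrices_square_symmetric_and_clustered(
        self, fixture_dir, compare_truth, tmp_path
    ):
        matrices = compare_all(
            fixture_dir / "compare", tmp_path, types=[ASType.SE], heatmap=False
        )
        m = matrices[(ASType.SE, "total")]
        n = len(m.names)
        assert m.p_matrix.shape == (n, n)
        assert (m.p_matrix.to_numpy() == m.p_matrix.to_numpy().T).all()
        assert (m.log_matrix.to_numpy() >= 0).all()
        labels = cluster_labels(m.log_matrix, 2)
        planted = compare_truth["clusters"]
        groups = {}
        for name, lab in labels.items():
            groups.setdefault(lab, set()).add(planted[name])
        assert all(len(v) == 1 for v in groups.values())  # pure clusters
        assert (tmp_path / "pvalue_matrix_SE_total.tsv").exists()
        assert (tmp_path / "experiment_summary.tsv").exists()

    def test_fewer_than_two_experiments_is_an_error(self, fixture_dir, tmp_path):
        single = tmp_path / "one"
        single.mkdir()
        src = next((fixture_dir / "compare").glob("expA1_SE.MATS.JCEC.txt"))
        (single / src.name).write_bytes(src.read_bytes())
        with pytest.raises(ValueError):
            compare_all(single, tmp_path / "out", types=[ASType.SE], heatmap=False)

    def test_non_conforming_files_ignored(self, fixture_dir, tmp_path):
        import shutil

        d = tmp_path / "dir"
        shutil.copytree(fixture_dir / "compare", d)
        (d / "README.txt").write_text("not an experiment\n")
        by_type, skipped = load_experiment_dir(d)
        assert len(by_type[ASType.SE]) == 6
        assert not skipped

    def test_corrupt_file_lands_in_skip_report(self, fixture_dir, tmp_path):
        import shutil

        d = tmp_path / "dir"
        shutil.copytree(fixture_dir / "compare", d)
        (d / "bad_SE.MATS.JCEC.txt").write_text("header\nnot\tenough\tcolumns\n")
        by_type, skipped = load_experiment_dir(d)
        assert len(skipped) == 1
        assert len(by_type[ASType.SE]) == 6

    def test_intersection_population_shrinks_n(self, fixture_dir):
        by_type, _ = load_experiment_dir(fixture_dir / "compare")
        a, b = by_type[ASType.SE][:2]
        union = pairwise_compare(a, b, "total", "union")
        inter = pairwise_compare(a, b, "total", "intersection")
        assert inter.N <= union.N
        assert inter.k == union.k  # same tested universe in this fixture

    def test_bh_adjustment_is_monotone_and_bounded(self, fixture_dir):
        from splicesuite.splice_compare import bh_adjust

        by_type, _ = load_experiment_dir(fixture_dir / "compare")
        m = compare_experiments(by_type[ASType.SE], "total")
        q = bh_adjust(m.p_matrix)
        raw = m.p_matrix.to_numpy()
        adj = q.to_numpy()
        iu = np.triu_indices_from(raw, k=1)
        assert (adj[iu] >= raw[iu] - 1e-15).all()
        assert (adj[iu] <= 1.0 + 1e-15).all()
        assert (adj == adj.T).all()

    def test_empty_directory_is_an_error(self, tmp_path):
        empty = tmp_path / "empty"
        empty.mkdir()
        with pytest.raises(ValueError, match="no parseable"):
            load_experiment_dir(empty)
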