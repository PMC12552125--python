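"""Statistics: BH correction, test selection, differential testing, PCA."""

import numpy as np
import pandas as pd
import pytest

from lipidkit.errors import (
    DomainError,
    InsufficientReplicatesError,
    InsufficientSamplesError,
)
from lipidkit.stats import (
    aggregate_replicates,
    bh_adjust,
    differential_test,
    pca_lipotypes,
    select_test,
)


def bh_reject_set(p: np.ndarray, alpha: float) -> set[int]:
    """Brute-force BH: reject the largest k with p_(k) <= k * alpha / m."""
    order = np.argsort(p, kind="stable")
    m = len(p)
    k = 0
    for i, idx in enumerate(order, start=1):
        if p[idx] <= i * alpha / m + 1e-12:  # tolerance for fp equality
            k = i
    return set(order[:k].tolist())


class TestBhAdjust:
    def test_single_value(self):
        np.testing.assert_allclose(bh_adjust([0.05]), [0.05])

    def test_worked_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(5)
        p = rng.random(15)
        q = bh_adjust(p)
        assert (q >= p - 1e-15).all()
        assert (q <= 1.0).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_matches_reject_set_definition(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 21)))
            q = bh_adjust(p)
            for alpha in np.concatenate([p, [0.01, 0.05, 0.1, 0.5, 1.0]]):
                expected = bh_reject_set(p, alpha)
                actual = {i for i, qi in enumerate(q) if qi <= alpha + 1e-12}
                assert actual == expected

    def test_domain_error(self):
        with pytest.raises(DomainError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(DomainError):
            bh_adjust([np.nan])


class TestSelectTest:
    def test_near_linear_groups_t(self):
        assert select_test([1, 2, 3, 4], [2, 3, 4, 6]) == "t"

    def test_outlier_selects_rank(self):
        assert select_test([1, 1, 1, 100], [2, 3, 4, 6]) == "mwu"

    def test_paired_well_behaved_differences(self):
        a = [1.0, 2.0, 3.0, 4.0]
        b = [1.9, 3.1, 5.2, 6.05]  # distinct, roughly symmetric differences
        assert select_test(a, b, paired=True) == "paired-t"

    def test_paired_outlier_difference(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [1.1, 2.1, 3.1, 4.1, 55.0]
        assert select_test(a, b, paired=True) == "wilcoxon"

    def test_insufficient_replicates(self):
        with pytest.raises(InsufficientReplicatesError):
            select_test([1, 2], [1, 2, 3])
        with pytest.raises(InsufficientReplicatesError):
            select_test([1, 2], [1, 2], paired=True)

    def test_constant_group_does_not_crash(self):
        assert select_test([5, 5, 5, 5], [1, 2, 3, 4]) in ("t", "mwu")


def _design(case, control):
    matrix = pd.DataFrame(
        [list(case) + list(control)],
        index=["f"],
        columns=[f"x{i}" for i in range(len(case))]
        + [f"c{i}" for i in range(len(control))])
    group_of = {f"x{i}": "case" for i in range(len(case))}
    group_of.update({f"c{i}": "ctrl" for i in range(len(control))})
    return matrix, group_of


class TestDifferentialTest:
    def test_identical_groups(self):
        matrix, group_of = _design([1, 2, 3, 4], [1, 2, 3, 4])
        res = differential_test(matrix, group_of, "case", "ctrl")
        row = res.table.loc["f"]
        assert row["log2fc"] == 0.0
        assert row["p"] == pytest.approx(1.0)

    def test_paired_t_worked_example(self):
        # differences [1, 1, 2, 2]: t = 1.5 / (0.5774 / 2) = 5.196, df = 3
        matrix, group_of = _design([2, 3, 5, 6], [1, 2, 3, 4])
        pair_of = {"x0": "p1", "x1": "p2", "x2": "p3", "x3": "p4",
                   "c0": "p1", "c1": "p2", "c2": "p3", "c3": "p4"}
        res = differential_test(matrix, group_of, "case", "ctrl", paired=True,
                                pair_of=pair_of, test_override="t")
        assert res.table.loc["f", "p"] == pytest.approx(0.013847, abs=1e-5)
        assert res.table.loc["f", "test"] == "paired-t"

    def test_bh_within_family(self):
        matrix = pd.DataFrame(
            np.zeros((3, 8)), index=list("abc"),
            columns=[f"x{i}" for i in range(4)] + [f"c{i}" for i in range(4)])
        group_of = {c: ("case" if c.startswith("x") else "ctrl")
                    for c in matrix.columns}
        res = differential_test(matrix + 1.0, group_of, "case", "ctrl")
        # identical data: all raw p = 1 -> all q = 1
        assert (res.table["q"] == 1.0).all()

    def test_skip_insufficient_values(self):
        matrix, group_of = _design([1.0, np.nan, np.nan, np.nan], [1, 2, 3, 4])
        res = differential_test(matrix, group_of, "case", "ctrl")
        row = res.table.loc["f"]
        assert bool(row["skipped"])
        assert np.isnan(row["p"]) and np.isnan(row["q"])

    def test_paired_drops_pairs_with_missing_member(self):
        matrix, group_of = _design([2, 3, 5, 6, np.nan], [1, 2, 3, 4, 9])
        pair_of = {f"x{i}": f"p{i}" for i in range(5)}
        pair_of.update({f"c{i}": f"p{i}" for i in range(5)})
        res = differential_test(matrix, group_of, "case", "ctrl", paired=True,
                                pair_of=pair_of, test_override="t")
        assert res.table.loc["f", "n_case"] == 4

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(8)
        matrix, group_of = _design(rng.normal(5, 1, 6), rng.normal(4, 1, 6))
        res_ab = differential_test(matrix, group_of, "case", "ctrl")
        res_ba = differential_test(matrix, group_of, "ctrl", "case")
        assert res_ab.table.loc["f", "p"] == pytest.approx(
            res_ba.table.loc["f", "p"])
        assert res_ab.table.loc["f", "log2fc"] == pytest.approx(
            -res_ba.table.loc["f", "log2fc"])
        assert res_ab.table.loc["f", "test"] == res_ba.table.loc["f", "test"]

    def test_missing_group_raises(self):
        matrix, group_of = _design([1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError):
            differential_test(matrix, group_of, "nope", "ctrl")


class TestAggregateReplicates:
    def test_experiment_means(self):
        matrix = pd.DataFrame({"a1": [1.0], "a2": [3.0], "b1": [5.0]},
                              index=["f"])
        replicate_of = {"a1": "e1", "a2": "e1", "b1": "e2"}
        group_of = {"a1": "g", "a2": "g", "b1": "g"}
        agg, agg_groups = aggregate_replicates(matrix, replicate_of, group_of)
        assert agg.loc["f", "g:e1"] == 2.0
        assert agg.loc["f", "g:e2"] == 5.0
        assert agg_groups == {"g:e1": "g", "g:e2": "g"}


class TestPca:
    def _two_cluster_matrix(self):
        rng = np.random.default_rng(9)
        n = 4
        left = rng.normal(0, 0.1, size=(5, n))
        right = rng.normal(0, 0.1, size=(5, n))
        left[0] += 10  # offset cluster along feature 0
        cols = [f"l{i}" for i in range(n)] + [f"r{i}" for i in range(n)]
        return pd.DataFrame(np.hstack([left, right]), columns=cols,
                            index=[f"f{i}" for i in range(5)])

    def test_two_clusters_separate_on_pc1(self):
        matrix = self._two_cluster_matrix()
        res = pca_lipotypes(matrix)
        left = res.scores.loc[[c for c in matrix.columns if c.startswith("l")],
                              "PC1"]
        right = res.scores.loc[[c for c in matrix.columns if c.startswith("r")],
                               "PC1"]
        assert (left.min() > right.max()) or (right.min() > left.max())
        assert res.explained_variance_ratio[0] > res.explained_variance_ratio[1]

    def test_duplicated_sample_identical_scores(self):
        matrix = self._two_cluster_matrix()
        matrix["dup"] = matrix["l0"]
        res = pca_lipotypes(matrix)
        np.testing.assert_allclose(res.scores.loc["dup"],
                                   res.scores.loc["l0"], atol=1e-9)

    def test_variance_fractions_match_eigendecomposition(self):
        matrix = self._two_cluster_matrix()
        res = pca_lipotypes(matrix)
        X = matrix.T.to_numpy()
        X = X - X.mean(axis=0)
        eigvals = np.linalg.eigvalsh(np.cov(X, rowvar=False))[::-1]
        expected = eigvals / eigvals.sum()
        np.testing.assert_allclose(res.explained_variance_ratio,
                                   expected[:len(res.explained_variance_ratio)],
                                   atol=1e-9)
        assert res.explained_variance_ratio.sum() <= 1.0 + 1e-9
        assert (np.diff(res.explained_variance_ratio) <= 1e-12).all()

    def test_missing_features_excluded(self):
        matrix = self._two_cluster_matrix()
        matrix.iloc[2, 0] = np.nan
        res = pca_lipotypes(matrix)
        assert "f2" not in res.loadings.index

    def test_insufficient_samples(self):
        with pytest.raises(InsufficientSamplesError):
            pca_lipotypes(pd.DataFrame({"s1": [1, 2], "s2": [2, 3]}))

    def test_sign_convention(self):
        matrix = self._two_cluster_matrix()
        res = pca_lipotypes(matrix)
        for comp in res.loadings.columns:
            lead = res.loadings[comp].abs().idxmax()
            assert res.loadings.loc[lead, comp] > 0
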