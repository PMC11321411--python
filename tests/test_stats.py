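"""Comparative statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from gnotofunc.config import AnalysisConfig
from gnotofunc.errors import DegenerateTableError, UndefinedIndexError
from gnotofunc.stats import (
    chisq_test,
    dissimilarity_index,
    group_ellipses,
    high_prevalence_filter,
    kruskal_dunn,
    pca_scores,
)


# ---------------------------------------------------------------------------
# high-prevalence filter
# ---------------------------------------------------------------------------

class TestHighPrevalenceFilter:
    def _presence(self, n_isolates, counts):
        # counts: module -> number of isolates carrying it
        data = {
            m: [i < c for i in range(n_isolates)] for m, c in counts.items()
        }
        return pd.DataFrame(data)

    def test_cutoff_at_29_isolates(self):
        presence = self._presence(29, {"kept23": 23, "removed24": 24})
        retained = high_prevalence_filter(presence, AnalysisConfig())
        assert retained == {"kept23"}

    def test_cutoff_n10(self):
        presence = self._presence(10, {"removed9": 9, "kept8": 8})
        retained = high_prevalence_filter(presence, AnalysisConfig())
        assert retained == {"kept8"}  # 9 > floor(0.8*10) = 8


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def _chisq_oracle(observed):
    """Textbook Pearson chi-squared, written out cell by cell."""
    observed = np.asarray(observed, dtype=float)
    n = observed.sum()
    stat = 0.0
    for i in range(observed.shape[0]):
        for j in range(observed.shape[1]):
            expected = observed[i].sum() * observed[:, j].sum() / n
            stat += (observed[i, j] - expected) ** 2 / expected
    df = (observed.shape[0] - 1) * (observed.shape[1] - 1)
    return stat, df


class TestChisq:
    def test_proportional_rows_give_zero(self):
        r = chisq_test(pd.DataFrame([[10, 20], [20, 40]]))
        assert r.statistic == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)

    def test_textbook_2x2(self):
        r = chisq_test(pd.DataFrame([[10, 20], [30, 40]]))
        assert r.statistic == pytest.approx(0.7937, abs=5e-4)
        assert r.df == 1

    def test_doubling_counts_doubles_statistic(self):
        t = pd.DataFrame([[5, 9, 2], [7, 3, 8]])
        assert chisq_test(2 * t).statistic == pytest.approx(
            2 * chisq_test(t).statistic
        )

    def test_matches_oracle_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            shape = (int(rng.integers(2, 5)), int(rng.integers(2, 5)))
            table = rng.integers(1, 30, size=shape)
            stat, df = _chisq_oracle(table)
            r = chisq_test(pd.DataFrame(table))
            assert r.statistic == pytest.approx(stat, rel=1e-10)
            assert r.df == df

    def test_permutation_invariance(self):
        t = pd.DataFrame([[5, 9, 2], [7, 3, 8], [1, 4, 6]])
        shuffled = t.iloc[[2, 0, 1], [1, 2, 0]]
        assert chisq_test(t).statistic == pytest.approx(
            chisq_test(shuffled).statistic
        )

    def test_zero_row_dropped_then_degenerate(self):
        with pytest.warns(UserWarning, match="all-zero"):
            with pytest.raises(DegenerateTableError):
                chisq_test(pd.DataFrame([[1, 2], [0, 0]]))


# ---------------------------------------------------------------------------
# dissimilarity index
# ---------------------------------------------------------------------------

class TestDissimilarity:
    def test_identical_members(self):
        m = pd.DataFrame([[1, 2], [1, 2], [1, 2]], index=list("abc"))
        idx = dissimilarity_index(m, "c")
        assert idx.pairwise_distances == [0.0, 0.0, 0.0]
        assert idx.median == 0.0

    def test_unit_difference(self):
        m = pd.DataFrame([[3, 1], [3, 2]])
        assert dissimilarity_index(m).pairwise_distances == [1.0]

    def test_pair_count(self):
        m = pd.DataFrame(np.arange(12).reshape(4, 3))
        assert len(dissimilarity_index(m).pairwise_distances) == 6

    def test_single_member_raises(self):
        with pytest.raises(UndefinedIndexError):
            dissimilarity_index(pd.DataFrame([[1, 2]]), "solo")


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def _kw_oracle(groups):
    """KW statistic from first principles (ranks + tie correction)."""
    pooled = [x for g in groups for x in g]
    order = sorted(range(len(pooled)), key=lambda i: pooled[i])
    ranks = [0.0] * len(pooled)
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and pooled[order[j]] == pooled[order[i]]:
            j += 1
        avg = (i + j + 1) / 2.0  # average of 1-based ranks i+1..j
        for k in range(i, j):
            ranks[order[k]] = avg
        i = j
    n = len(pooled)
    pos = 0
    h = 0.0
    for g in groups:
        r = sum(ranks[pos:pos + len(g)])
        h += r * r / len(g)
        pos += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    counts = {}
    for x in pooled:
        counts[x] = counts.get(x, 0) + 1
    correction = 1 - sum(c**3 - c for c in counts.values()) / (n**3 - n)
    return h / correction if correction else 0.0


class TestKruskalDunn:
    def test_identical_groups_large_p(self):
        r = kruskal_dunn([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        assert r.p >= 0.9
        assert (r.pairwise["p"] == 1.0).all()

    def test_statistic_matches_rank_oracle(self):
        groups = [[1, 2, 3], [11, 12, 13], [21, 22, 23]]
        r = kruskal_dunn(groups)
        assert r.statistic == pytest.approx(_kw_oracle(groups), rel=1e-12)

    def test_random_small_groups_match_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            groups = [
                list(rng.integers(0, 12, size=rng.integers(2, 9)))
                for _ in range(int(rng.integers(3, 5)))
            ]
            pooled = [x for g in groups for x in g]
            if len(set(pooled)) == 1:
                continue
            r = kruskal_dunn(groups)
            assert r.statistic == pytest.approx(_kw_oracle(groups), rel=1e-9)

    def test_group_permutation_leaves_statistic_unchanged(self):
        groups = [[1, 5, 3], [9, 2, 8], [4, 7, 6]]
        r1 = kruskal_dunn(groups)
        r2 = kruskal_dunn([groups[2], groups[0], groups[1]])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_dunn_z_matches_direct_formula(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        r = kruskal_dunn(groups)
        # all-distinct data: mean ranks are 2, 5, 8 of N=9
        n = 9
        se = math.sqrt(n * (n + 1) / 12 * (1 / 3 + 1 / 3))
        z01 = (2 - 5) / se
        row = r.pairwise.iloc[0]
        assert row["z"] == pytest.approx(z01)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2"):
            kruskal_dunn([[1], [2, 3], [4, 5]])


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

class TestPca:
    def test_identical_rows_degenerate(self):
        m = pd.DataFrame([[1, 2, 3]] * 4)
        r = pca_scores(m)
        assert r.degenerate
        assert (r.scores.to_numpy() == 0).all()

    def test_rank_one_matrix(self):
        m = pd.DataFrame([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0]])
        r = pca_scores(m)
        assert r.explained_variance_ratio[0] == pytest.approx(1.0)

    def test_matches_eigendecomposition_oracle(self):
        m = pd.DataFrame([[0.0, 0.0], [1.0, 0.5], [0.2, 2.0]])
        X = m.to_numpy() - m.to_numpy().mean(axis=0)
        eigvals, eigvecs = np.linalg.eigh(X.T @ X / (len(m) - 1))
        order = np.argsort(eigvals)[::-1]
        expected = np.abs(X @ eigvecs[:, order])
        r = pca_scores(m)
        assert np.allclose(np.abs(r.scores.to_numpy()), expected, atol=1e-8)

    def test_scores_centered_and_order_invariant(self):
        rng = np.random.default_rng(9)
        m = pd.DataFrame(rng.normal(size=(6, 4)))
        r = pca_scores(m)
        assert np.allclose(r.scores.to_numpy().mean(axis=0), 0.0, atol=1e-10)
        perm = [3, 1, 5, 0, 4, 2]
        r2 = pca_scores(m.iloc[perm])
        assert np.allclose(
            np.abs(r2.scores.to_numpy()),
            np.abs(r.scores.to_numpy()[perm]),
            atol=1e-8,
        )

    def test_group_ellipses_shape(self):
        rng = np.random.default_rng(2)
        m = pd.DataFrame(rng.normal(size=(8, 3)),
                         index=[f"g{i}" for i in range(8)])
        r = pca_scores(m)
        groups = pd.Series(
            ["a"] * 4 + ["b"] * 4, index=m.index
        )
        ell = group_ellipses(r.scores, groups)
        assert set(ell["group"]) == {"a", "b"}
        assert (ell["semi_major"] >= ell["semi_minor"]).all()
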