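"""Inferential statistics against independent oracles and known fixtures."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from homenet.datasets import victorian_wfh_survey
from homenet.stats import (
    ContingencyTable,
    censored_pearson,
    fisher_exact_or,
    morans_i,
    pca_three_vars,
    two_sample_t,
)


def exact_fisher_p(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric enumeration with
    exact rational arithmetic."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(a + b + c + d, c1)
    observed = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= observed:
            total += pk
    return float(total)


def grid_adjacency(side):
    ids = [f"g{i:03d}" for i in range(side * side)]
    pairs = []
    for i in range(side * side):
        x, y = divmod(i, side)
        for dx, dy in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            nx, ny = x + dx, y + dy
            if 0 <= nx < side and 0 <= ny < side:
                pairs.append((ids[i], ids[nx * side + ny]))
    return ids, pd.DataFrame(pairs, columns=["region_id", "neighbour_id"])


class TestCensoredPearson:
    def test_perfect_line(self):
        x = np.arange(20.0)
        res = censored_pearson(x, 2 * x + 1)
        assert res.rho == pytest.approx(1.0)
        assert res.ci_low == pytest.approx(1.0) and res.n_censored == 0

    def test_independent_variables_stay_small(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            res = censored_pearson(rng.normal(size=500), rng.normal(size=500))
            hits += abs(res.rho) < 0.15
        assert hits >= 38  # >= 95% of replicates

    def test_outlier_pair_censored_matches_brute_force(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 100)
        y = 0.5 * x + rng.normal(0, 1, 100)
        x[0] = 10 * np.std(x)  # plant one wild pair
        res = censored_pearson(x, y)
        assert res.n_censored == 1
        keep = np.abs(x - x.mean()) <= 3 * x.std(ddof=1)
        expected = np.corrcoef(x[keep], y[keep])[0, 1]
        assert res.rho == pytest.approx(expected, abs=1e-12)
        assert res.ci_low <= res.rho <= res.ci_high

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=50), rng.normal(size=50)
        a, b = censored_pearson(x, y), censored_pearson(y, x)
        assert a.rho == pytest.approx(b.rho)
        assert a.n_censored == b.n_censored

    @given(scale=st.floats(0.1, 50), shift=st.floats(-100, 100))
    @settings(max_examples=25, deadline=None)
    def test_positive_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=60), rng.normal(size=60)
        a = censored_pearson(x, y)
        b = censored_pearson(scale * x + shift, y)
        assert a.rho == pytest.approx(b.rho, abs=1e-9)
        assert a.n_censored == b.n_censored

    def test_zero_variance_reported_undefined(self):
        res = censored_pearson(np.ones(10), np.arange(10.0))
        assert not res.defined and math.isnan(res.rho)


class TestTwoSampleT:
    def test_identical_groups_p_one(self):
        x = np.arange(10.0)
        res = two_sample_t(x, x)
        assert res.pvalue == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_five_sd_shift_tiny_p(self):
        rng = np.random.default_rng(8)
        a = rng.normal(0, 1, 100)
        b = rng.normal(5, 1, 100)
        assert two_sample_t(a, b).pvalue < 1e-6

    def test_matches_manual_welch_formula(self):
        a = np.array([1.0, 2.0, 3.0])
        b = np.array([2.0, 4.0, 9.0])
        res = two_sample_t(a, b)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t_manual = (a.mean() - b.mean()) / math.sqrt(va + vb)
        assert res.statistic == pytest.approx(t_manual, abs=1e-12)

    def test_pooled_option(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 3.0, 5.0])
        welch = two_sample_t(a, b, equal_var=False)
        pooled = two_sample_t(a, b, equal_var=True)
        assert pooled.df == len(a) + len(b) - 2
        assert welch.df != pooled.df


class TestFisherExact:
    def test_published_survey_table(self):
        res = fisher_exact_or(victorian_wfh_survey())
        assert round(res.odds_ratio, 2) == 2.15
        assert round(res.ci_low, 2) == 1.59
        assert round(res.ci_high, 2) == 2.92
        assert res.p_two_tailed == pytest.approx(6.8e-7, rel=0.05)

    def test_symmetric_table(self):
        res = fisher_exact_or(ContingencyTable(10, 10, 10, 10))
        assert res.odds_ratio == 1.0 and res.p_two_tailed == pytest.approx(1.0)

    def test_small_table_matches_enumeration(self):
        res = fisher_exact_or(ContingencyTable(5, 3, 2, 7))
        assert res.p_two_tailed == pytest.approx(exact_fisher_p(5, 3, 2, 7),
                                                 rel=1e-10)

    def test_exact_ci_contains_or_and_differs_from_normal(self):
        t = victorian_wfh_survey()
        normal = fisher_exact_or(t, ci_method="normal")
        exact = fisher_exact_or(t, ci_method="exact")
        for res in (normal, exact):
            assert res.ci_low <= res.odds_ratio <= res.ci_high
        assert normal.ci_low != exact.ci_low

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margins"):
            fisher_exact_or(ContingencyTable(0, 0, 5, 5))

    def test_degenerate_cell_flagged_with_ci(self):
        res = fisher_exact_or(ContingencyTable(5, 0, 2, 7))
        assert res.degenerate and res.odds_ratio == math.inf
        assert res.ci_method == "haldane"
        assert 0 < res.ci_low < res.ci_high


class TestMoransI:
    def test_checkerboard_is_negative(self):
        ids, adj = grid_adjacency(6)
        values = pd.Series([(i // 6 + i % 6) % 2 for i in range(36)],
                           index=ids, dtype=float)
        res = morans_i(values, adj, n_permutations=99, seed=0)
        assert res.I < 0

    def test_smooth_gradient_significant(self):
        ids, adj = grid_adjacency(10)
        rng = np.random.default_rng(2)
        values = pd.Series([i % 10 + rng.normal(0, 0.1)
                            for i in range(100)], index=ids)
        res = morans_i(values, adj, n_permutations=999, seed=0)
        assert res.I > 0
        assert res.p_permutation <= 0.001
        assert res.expected_I == pytest.approx(-1 / 99)

    def test_random_values_near_null_expectation(self):
        ids, adj = grid_adjacency(10)
        stats = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            values = pd.Series(rng.normal(size=100), index=ids)
            stats.append(morans_i(values, adj, n_permutations=99,
                                  seed=seed).I)
        assert abs(np.mean(stats) - (-1 / 99)) < 0.03

    def test_seeded_permutation_reproducible(self):
        ids, adj = grid_adjacency(5)
        rng = np.random.default_rng(3)
        values = pd.Series(rng.normal(size=25), index=ids)
        a = morans_i(values, adj, n_permutations=199, seed=42)
        b = morans_i(values, adj, n_permutations=199, seed=42)
        assert a == b

    def test_fully_isolated_map_undefined(self):
        values = pd.Series([1.0, 2.0, 3.0, 4.0],
                           index=["a", "b", "c", "d"])
        adj = pd.DataFrame(columns=["region_id", "neighbour_id"])
        res = morans_i(values, adj, n_permutations=99, seed=0)
        assert not res.defined


class TestPCA:
    def test_duplicated_signal_dominates_first_component(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=400)
        df = pd.DataFrame({"a": x, "b": x + rng.normal(0, 0.05, 400),
                           "c": rng.normal(size=400)})
        res = pca_three_vars(df)
        assert res.variance_explained[0] >= 2 / 3

    def test_independent_variables_split_evenly(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(5000, 3)), columns=list("abc"))
        res = pca_three_vars(df)
        np.testing.assert_allclose(res.variance_explained, 1 / 3, atol=0.05)

    def test_sign_flip_of_input_flips_only_its_loadings(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=300)
        df = pd.DataFrame({"a": x, "b": 0.7 * x + rng.normal(0, 0.7, 300),
                           "c": rng.normal(size=300)})
        res = pca_three_vars(df)
        flipped = pca_three_vars(df.assign(c=-df["c"]))
        np.testing.assert_allclose(res.variance_explained,
                                   flipped.variance_explained, atol=1e-10)
        np.testing.assert_allclose(np.abs(res.loadings.loc["c"]),
                                   np.abs(flipped.loadings.loc["c"]),
                                   atol=1e-8)

    def test_loadings_unit_norm_and_variance_ordered(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(100, 3)), columns=list("abc"))
        res = pca_three_vars(df)
        np.testing.assert_allclose((res.loadings ** 2).sum(axis=0), 1.0,
                                   atol=1e-10)
        assert (np.diff(res.variance_explained) <= 1e-12).all()

    def test_constant_variable_excluded_with_warning(self):
        rng = np.random.default_rng(13)
        df = pd.DataFrame({"a": rng.normal(size=50), "b": np.ones(50),
                           "c": rng.normal(size=50)})
        with pytest.warns(UserWarning, match="constant"):
            res = pca_three_vars(df)
        assert list(res.loadings.index) == ["a", "c"]
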