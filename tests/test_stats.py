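"""Exact Mann-Whitney and Spearman statistics against enumeration oracles."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, spearmanr

from petkin import (
    InvalidInputError,
    TieError,
    cohort_compare,
    exact_mann_whitney,
    min_attainable_p,
    spearman,
)


def brute_force_mwu_p(x, y):
    """Two-tailed p by explicit enumeration of all group assignments."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    u_obs = sum(xi > yi for xi in x for yi in y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        a = pooled[list(idx)]
        b = np.delete(pooled, list(idx))
        us.append(sum(ai > bi for ai in a for bi in b))
    us = np.array(us)
    lower = np.mean(us <= u_obs)
    upper = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lower, upper))


class TestExactMannWhitney:
    def test_complete_separation_5v3(self):
        res = exact_mann_whitney([1, 2, 3, 4, 5], [6, 7, 8])
        assert res.u == 0
        assert res.p == pytest.approx(2 / 56)

    def test_complete_separation_3v3(self):
        assert exact_mann_whitney([1, 2, 3], [4, 5, 6]).p == pytest.approx(0.1)

    def test_symmetric_under_group_swap(self):
        x, y = [0.3, 1.7, 2.2], [0.9, 4.1]
        assert exact_mann_whitney(x, y).p == exact_mann_whitney(y, x).p

    @pytest.mark.parametrize("n1,n2", [(n1, n2) for n1 in range(1, 6) for n2 in range(1, 6) if n1 + n2 <= 10])
    def test_matches_enumeration_oracle(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        x = rng.normal(size=n1)
        y = rng.normal(size=n2) + rng.uniform(-1, 1)
        assert exact_mann_whitney(x, y).p == pytest.approx(brute_force_mwu_p(x, y), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            x = rng.normal(size=5)
            y = rng.normal(size=4) + 0.5
            ref = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            assert exact_mann_whitney(x, y).p == pytest.approx(ref, rel=1e-12)

    @settings(derandomize=True, max_examples=30)
    @given(seed=st.integers(0, 5000), shift=st.floats(0.1, 3.0))
    def test_invariant_under_monotone_transform(self, seed, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=4)
        y = rng.normal(size=3) + shift
        p0 = exact_mann_whitney(x, y).p
        f = lambda v: np.exp(3 * np.asarray(v)) + 1  # strictly increasing
        assert exact_mann_whitney(f(x), f(y)).p == pytest.approx(p0, abs=1e-12)

    @pytest.mark.parametrize("n1,n2,expected", [(5, 3, 2 / 56), (4, 3, 2 / 35), (3, 3, 0.1)])
    def test_minimum_attainable_two_tailed_p(self, n1, n2, expected):
        assert min_attainable_p(n1, n2) == pytest.approx(expected)
        x = list(range(n1))
        y = list(range(n1, n1 + n2))
        assert exact_mann_whitney(x, y).p == pytest.approx(expected)

    def test_ties_rejected(self):
        with pytest.raises(TieError):
            exact_mann_whitney([1, 2, 2], [3, 4])


class TestSpearman:
    def test_perfect_monotone(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11]
        y = np.exp(np.array(x))  # monotone, nonlinear
        res = spearman(x, y)
        assert res.rho == pytest.approx(1.0)
        assert res.p == pytest.approx(0.0, abs=1e-12)
        assert spearman(x, y[::-1]).rho == pytest.approx(-1.0)

    def test_rho_matches_rank_formula_n11(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=11)
        y = rng.normal(size=11)
        rx = np.argsort(np.argsort(x)) + 1.0
        ry = np.argsort(np.argsort(y)) + 1.0
        d2 = float(((rx - ry) ** 2).sum())
        expected = 1 - 6 * d2 / (11 * (11**2 - 1))
        assert spearman(x, y).rho == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=15)
        y = 0.5 * x + rng.normal(size=15)
        res = spearman(x, y)
        ref = spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_exact_p_small_n_hand_computed(self):
        # n = 3, perfectly concordant: of 3! = 6 permutations, only the
        # identity and the reversal reach |rho| = 1, so p = 2/6
        res = spearman([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert res.exact
        assert res.p == pytest.approx(2 / 6)

    def test_exact_p_is_valid_and_positive(self):
        rng = np.random.default_rng(21)
        res = spearman(rng.normal(size=7), rng.normal(size=7))
        assert res.exact and 0 < res.p <= 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            spearman([1, 2, 3], [1, 2])


class TestCohortCompare:
    def make_table(self, case_vals, control_vals, metric="Ki"):
        rows = [{"subject_id": f"c{i}", "group": "case", metric: v} for i, v in enumerate(case_vals)]
        rows += [{"subject_id": f"h{i}", "group": "control", metric: v} for i, v in enumerate(control_vals)]
        return pd.DataFrame(rows)

    def test_complete_separation_headline_p(self):
        table = self.make_table([6, 7, 8, 9, 10], [1, 2, 3])
        res = cohort_compare(table, ["Ki"], case_label="case")
        assert res.loc[0, "p"] == pytest.approx(0.0357, abs=1e-4)
        assert bool(res.loc[0, "significant"])

    def test_leave_one_out_sensitivity(self):
        # dropping the extreme case subject: 4-vs-3 complete separation
        table = self.make_table([6, 7, 8, 9], [1, 2, 3])
        res = cohort_compare(table, ["Ki"], case_label="case")
        assert res.loc[0, "p"] == pytest.approx(0.0571, abs=1e-4)
        assert not bool(res.loc[0, "significant"])

    def test_substituting_extreme_with_group_minimum_keeps_p(self):
        # replacing the top case value by (just below) the within-group minimum
        # preserves complete separation, so p stays at 0.036
        base = cohort_compare(self.make_table([6, 7, 8, 9, 10], [1, 2, 3]), ["Ki"])
        subst = cohort_compare(self.make_table([6, 7, 8, 9, 5.9], [1, 2, 3]), ["Ki"])
        assert subst.loc[0, "p"] == base.loc[0, "p"] == pytest.approx(2 / 56)

    def test_interleaved_groups_not_significant(self):
        res = cohort_compare(self.make_table([1, 3, 5], [2, 4, 6]), ["Ki"])
        assert res.loc[0, "p"] > 0.5

    def test_bonferroni_column_reported_but_not_applied(self):
        table = self.make_table([6, 7, 8, 9, 10], [1, 2, 3], metric="m1")
        table["m2"] = list(range(8))
        res = cohort_compare(table, ["m1", "m2"], case_label="case")
        row = res[res["metric"] == "m1"].iloc[0]
        assert row["p_bonferroni"] == pytest.approx(2 * row["p"])
        assert bool(row["significant"])  # flag uses the unadjusted p

    def test_empty_group_rejected(self):
        table = self.make_table([1, 2, 3], [])
        with pytest.raises(InvalidInputError):
            cohort_compare(table, ["Ki"])
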