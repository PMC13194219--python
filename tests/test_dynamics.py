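"""Peak-function evaluation and fitting, Kendall tau, rank tests.

Independent oracles: brute-force O(n^2) pair counting for tau, the tau-b
closed form under ties, the explicit rank formula for the Kruskal-Wallis H,
and the Mann-Whitney z-transform for the two-group case.
"""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from trunkvoc.dynamics import (
    ExtremeParams,
    daily_aggregate,
    dunn_posthoc,
    eval_extreme,
    fit_extreme,
    kendall_tau,
    kruskal_wallis,
    tau_group,
)


def brute_force_tau(x, y):
    """O(n^2) concordant/discordant pair counting; tau-b with ties."""
    n = len(x)
    C = D = tx = ty = 0
    for i, j in itertools.combinations(range(n), 2):
        a, b = x[i] - x[j], y[i] - y[j]
        if a == 0 and b == 0:
            tx += 1
            ty += 1
        elif a == 0:
            tx += 1
        elif b == 0:
            ty += 1
        elif a * b > 0:
            C += 1
        else:
            D += 1
    n0 = n * (n - 1) / 2
    return (C - D) / math.sqrt((n0 - tx) * (n0 - ty))


def rank_formula_H(groups):
    """Independent H: 12/(N(N+1)) * sum n_i (Rbar_i - (N+1)/2)^2, tie-corrected."""
    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    N = len(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        start += len(g)
        H += len(g) * (r.mean() - (N + 1) / 2) ** 2
    H *= 12.0 / (N * (N + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return H / tie


class TestDailyAggregate:
    def test_duplicate_mean_and_sem(self):
        df = pd.DataFrame({"day": [1, 1], "rate": [4.0, 6.0]})
        out = daily_aggregate(df)
        assert out.loc[0, "mean"] == 5.0
        assert out.loc[0, "sem"] == pytest.approx(1.0)  # |a-b|/2

    def test_single_replicate_sem_undefined(self):
        out = daily_aggregate(pd.DataFrame({"day": [3], "rate": [7.0]}))
        assert out.loc[0, "mean"] == 7.0 and np.isnan(out.loc[0, "sem"])

    def test_equal_replicates_sem_zero(self):
        out = daily_aggregate(pd.DataFrame({"day": [1, 1], "rate": [3.0, 3.0]}))
        assert out.loc[0, "sem"] == 0.0


class TestEvalExtreme:
    def test_peak_value_at_xc(self):
        p = ExtremeParams(y0=2.0, A=5.0, xc=30.0, w=4.0)
        assert eval_extreme(p, 30.0) == pytest.approx(7.0, rel=1e-14)

    def test_right_asymptote_is_offset(self):
        p = ExtremeParams(y0=1.5, A=5.0, xc=30.0, w=4.0)
        assert eval_extreme(p, 1e6) == pytest.approx(1.5, rel=1e-9)

    def test_unit_evaluation(self):
        # y0=0, A=1, xc=0, w=1 at x=1: exp(-exp(-1)) ~ 0.69220
        p = ExtremeParams(y0=0.0, A=1.0, xc=0.0, w=1.0)
        assert eval_extreme(p, 1.0) == pytest.approx(math.exp(-math.exp(-1)), rel=1e-12)
        assert eval_extreme(p, 1.0) == pytest.approx(0.69220, abs=5e-6)

    def test_maximum_attained_at_xc_on_fine_grid(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            p = ExtremeParams(
                y0=rng.uniform(0, 5), A=rng.uniform(0.5, 10),
                xc=rng.uniform(20, 150), w=rng.uniform(2, 30),
            )
            x = np.linspace(p.xc - 8 * p.w, p.xc + 8 * p.w, 4001)
            y = eval_extreme(p, x)
            assert abs(x[np.argmax(y)] - p.xc) <= (x[1] - x[0]) + 1e-12
            assert y.max() <= p.y0 + p.A + 1e-12


class TestFitExtreme:
    def test_noiseless_self_consistency(self):
        truth = ExtremeParams(y0=0.5, A=8.0, xc=60.0, w=12.0)
        days = np.arange(20, 140, 3, dtype=float)
        series = pd.DataFrame({"day": days, "mean": eval_extreme(truth, days)})
        fit = fit_extreme(series, seed=0)
        assert fit.converged
        assert fit.params.xc == pytest.approx(truth.xc, rel=1e-4)
        assert fit.params.A == pytest.approx(truth.A, rel=1e-4)
        assert fit.adj_r2 > 0.9999

    def test_constant_series_rejected(self):
        series = pd.DataFrame({"day": np.arange(10.0), "mean": np.ones(10)})
        with pytest.raises(ValueError):
            fit_extreme(series)

    def test_too_few_points_rejected(self):
        series = pd.DataFrame({"day": [1.0, 2, 3, 4], "mean": [1.0, 2, 3, 1]})
        with pytest.raises(ValueError):
            fit_extreme(series)

    def test_adj_r2_penalizes_noise(self):
        """Noisy data: adjusted R^2 stays below the raw R^2 ceiling of 1."""
        truth = ExtremeParams(y0=0.5, A=8.0, xc=60.0, w=12.0)
        rng = np.random.default_rng(5)
        days = np.arange(20, 140, 3, dtype=float)
        y = eval_extreme(truth, days) * rng.lognormal(0, 0.15, len(days))
        fit = fit_extreme(pd.DataFrame({"day": days, "mean": y}), seed=0)
        assert fit.converged and fit.adj_r2 < 1.0


class TestKendallTau:
    def test_identical_series_tau_one(self):
        s = pd.Series([1.0, 3, 2, 5, 4], index=range(5))
        tau, _ = kendall_tau(s, s)
        assert tau == pytest.approx(1.0)

    def test_reversed_series_tau_minus_one(self):
        s = pd.Series([1.0, 2, 3, 4, 5], index=range(5))
        tau, _ = kendall_tau(s, s.iloc[::-1].set_axis(s.index))
        assert tau == pytest.approx(-1.0)

    def test_brute_force_example(self):
        # (1,2,3,4) vs (1,3,2,4): 5 concordant, 1 discordant -> 4/6
        x = pd.Series([1.0, 2, 3, 4])
        y = pd.Series([1.0, 3, 2, 4])
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(4 / 6)
        assert tau == pytest.approx(brute_force_tau(x.values, y.values))

    def test_alignment_on_shared_days_only(self):
        x = pd.Series([1.0, 2, 3, 4], index=[1, 2, 3, 4])
        y = pd.Series([1.0, 2, 3, 4], index=[2, 3, 4, 5])
        tau, _ = kendall_tau(x, y)
        assert tau == pytest.approx(1.0)

    def test_too_few_shared_days_is_error(self):
        x = pd.Series([1.0, 2], index=[1, 2])
        with pytest.raises(ValueError):
            kendall_tau(x, x)

    def test_matches_brute_force_with_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = rng.integers(5, 15)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            tau, _ = kendall_tau(pd.Series(x), pd.Series(y))
            assert tau == pytest.approx(brute_force_tau(x, y), abs=1e-12)


class TestTauGrouping:
    def test_mutually_correlated_form_one_group(self):
        base = pd.Series(np.arange(10.0))
        series = {k: base + i for i, k in enumerate("abc")}
        g = tau_group(series, tau_min=0.9)
        assert g.groups[0] == {"a", "b", "c"}

    def test_uncorrelated_stay_singletons(self):
        rng = np.random.default_rng(0)
        series = {k: pd.Series(rng.permutation(12).astype(float)) for k in "abc"}
        g = tau_group(series, tau_min=0.95)
        assert all(len(grp) == 1 for grp in g.groups)

    def test_single_linkage_chains_transitively(self):
        """A-B and B-C above threshold group {A,B,C} even if A-C is below."""
        n = 30
        a = np.arange(n, dtype=float)

        def head_reversed(x, k):
            y = x.copy()
            y[:k] = y[:k][::-1]
            return y

        sa = pd.Series(a)
        sb = pd.Series(head_reversed(a, 7))  # tau(a,b) ~ 0.903
        sc = pd.Series(head_reversed(a, 10))  # tau(b,c) ~ 0.890, tau(a,c) ~ 0.793
        tau_min = 0.85
        t_ab, p_ab = kendall_tau(sa, sb)
        t_bc, p_bc = kendall_tau(sb, sc)
        t_ac, _ = kendall_tau(sa, sc)
        assert t_ab >= tau_min and t_bc >= tau_min and t_ac < tau_min
        assert p_ab < 0.001 and p_bc < 0.001
        g = tau_group({"A": sa, "B": sb, "C": sc}, tau_min=tau_min)
        assert g.groups[0] == {"A", "B", "C"}

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(1)
        series = {k: pd.Series(rng.normal(size=15)) for k in "abcd"}
        g = tau_group(series)
        assert np.allclose(g.tau.values, g.tau.values.T, equal_nan=True)
        assert np.allclose(np.diag(g.tau.values), 1.0)


class TestKruskalWallis:
    def test_identical_groups_h_zero(self):
        H, p = kruskal_wallis([[1.0, 1, 1], [1.0, 1, 1]])
        assert H == 0.0 and p == 1.0

    def test_matches_independent_rank_formula(self):
        groups = [[1.0, 2, 3], [4.0, 5, 6], [7.0, 8, 9]]
        H, _ = kruskal_wallis(groups)
        assert H == pytest.approx(rank_formula_H(groups), abs=1e-12)
        assert H == pytest.approx(7.2)

    def test_rank_formula_agreement_with_ties(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            groups = [rng.integers(0, 6, rng.integers(3, 10)).astype(float)
                      for _ in range(3)]
            if np.ptp(np.concatenate(groups)) == 0:
                continue
            H, _ = kruskal_wallis(groups)
            assert H == pytest.approx(rank_formula_H(groups), abs=1e-10)

    def test_two_group_case_equals_mann_whitney_transform(self):
        """Tie-free two-group H equals the squared standardized U statistic."""
        rng = np.random.default_rng(17)
        a = rng.normal(size=12)
        b = rng.normal(1.0, 1.0, size=15)
        H, _ = kruskal_wallis([a, b])
        U = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        n1, n2 = len(a), len(b)
        z = (U - n1 * n2 / 2) / math.sqrt(n1 * n2 * (n1 + n2 + 1) / 12)
        assert H == pytest.approx(z**2, abs=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0], []])


class TestDunnPosthoc:
    def test_identical_groups_all_p_one(self):
        out = dunn_posthoc({"a": [1.0, 1, 1], "b": [1.0, 1, 1], "c": [1.0, 1, 1]})
        assert (out["p"] == 1.0).all()

    def test_far_shifted_group_flagged(self):
        groups = {
            "a": [1.0, 2, 3, 4, 5], "b": [2.0, 3, 4, 5, 6],
            "c": [1001.0, 1002, 1003, 1004, 1005],
        }
        out = dunn_posthoc(groups).set_index(["group1", "group2"])
        assert out.loc[("a", "c"), "significant"]
        assert out.loc[("b", "c"), "significant"]
        assert not out.loc[("a", "b"), "significant"]

    def test_holm_dominates_unadjusted(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(i, 1, 8).tolist() for i, k in enumerate("abcd")}
        raw = dunn_posthoc(groups, adjust="none")
        holm = dunn_posthoc(groups, adjust="holm")
        assert (holm["p_adjusted"].values >= raw["p_adjusted"].values - 1e-15).all()

    def test_z_matches_hand_computed_mean_ranks(self):
        """Tie-free: z = (Rbar_i - Rbar_j) / sqrt(N(N+1)/12 (1/n_i + 1/n_j))."""
        groups = {"a": [1.0, 3, 5], "b": [2.0, 4, 6, 8]}
        out = dunn_posthoc(groups)
        ranks = stats.rankdata([1, 3, 5, 2, 4, 6, 8])
        ra, rb = ranks[:3].mean(), ranks[3:].mean()
        N = 7
        se = math.sqrt(N * (N + 1) / 12 * (1 / 3 + 1 / 4))
        assert out.loc[0, "z"] == pytest.approx((ra - rb) / se, abs=1e-12)
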