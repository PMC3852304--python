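"""Univariate screening, correlation pruning and bootstrap model selection."""

import numpy as np
import pandas as pd
import pytest

from ntcpkit.cohort import CohortSpec, generate_cohort
from ntcpkit.logistic import LogisticNTCP
from ntcpkit.selection import (
    UnivariateResult,
    _fit_subsets,
    bootstrap_select,
    prune_correlated,
    spearman_matrix,
    spearman_screen,
)
from scipy.special import expit


def _frame(**cols) -> pd.DataFrame:
    return pd.DataFrame(cols)


class TestSpearmanScreen:
    def test_perfect_concordance(self):
        y = np.r_[np.zeros(5), np.ones(5)]
        df = _frame(late_gi=y, x=y.copy())
        (res,) = spearman_screen(df, ["x"])
        assert res.rs == pytest.approx(1.0)

    def test_four_point_rank_correlation(self):
        df = _frame(late_gi=[0, 0, 1, 1], x=[1.0, 2.0, 3.0, 4.0])
        (res,) = spearman_screen(df, ["x"])
        assert res.rs == pytest.approx(0.8944, abs=1e-3)

    def test_constant_variable_flagged(self):
        df = _frame(late_gi=[0, 1, 0, 1], x=[2.0, 2.0, 2.0, 2.0])
        (res,) = spearman_screen(df, ["x"])
        assert res.degenerate and res.rs == 0.0

    def test_null_variable_small_correlation(self):
        rng = np.random.default_rng(0)
        n = 5000
        df = _frame(late_gi=rng.integers(0, 2, n).astype(float), x=rng.normal(size=n))
        (res,) = spearman_screen(df, ["x"])
        assert abs(res.rs) < 0.05


class TestPruneCorrelated:
    @staticmethod
    def _correlated_pair(seed=0, n=200):
        """v60/v65 surrogates: pairwise correlation ~0.98, v65 slightly
        stronger against the outcome (as in the reference univariate table,
        |rs| 0.282 vs 0.284)."""
        rng = np.random.default_rng(seed)
        latent = rng.normal(size=n)
        v60 = latent + 0.1 * rng.normal(size=n)
        v65 = latent + 0.1 * rng.normal(size=n)
        y = (latent + rng.normal(size=n) > 0).astype(float)
        return _frame(late_gi=y, v60=v60, v65=v65)

    def test_weaker_member_of_pair_dropped(self):
        df = self._correlated_pair()
        screen = [
            UnivariateResult("v60", 0.282, 0.034),
            UnivariateResult("v65", 0.284, 0.032),
        ]
        assert prune_correlated(df, ["v60", "v65"], screen) == ["v65"]

    def test_no_pair_above_threshold_is_identity(self):
        rng = np.random.default_rng(1)
        df = _frame(a=rng.normal(size=100), b=rng.normal(size=100))
        screen = [UnivariateResult("a", 0.3, 0.1), UnivariateResult("b", 0.2, 0.1)]
        assert set(prune_correlated(df, ["a", "b"], screen)) == {"a", "b"}

    def test_three_mutually_correlated_one_survivor(self):
        rng = np.random.default_rng(2)
        latent = rng.normal(size=300)
        df = _frame(
            a=latent + 0.05 * rng.normal(size=300),
            b=latent + 0.05 * rng.normal(size=300),
            c=latent + 0.05 * rng.normal(size=300),
        )
        screen = [
            UnivariateResult("a", 0.20, 0.1),
            UnivariateResult("b", 0.35, 0.1),
            UnivariateResult("c", 0.28, 0.1),
        ]
        assert prune_correlated(df, ["a", "b", "c"], screen) == ["b"]

    def test_result_independent_of_input_order(self):
        df = self._correlated_pair(seed=3)
        df["noise"] = np.random.default_rng(4).normal(size=len(df))
        screen = [
            UnivariateResult("v60", 0.282, 0.03),
            UnivariateResult("v65", 0.284, 0.03),
            UnivariateResult("noise", 0.01, 0.9),
        ]
        a = prune_correlated(df, ["v60", "v65", "noise"], screen)
        b = prune_correlated(df, ["noise", "v65", "v60"], screen)
        assert a == b


class TestBatchedFitter:
    def test_matches_single_model_newton(self, default_cohort):
        """The batched subset solver agrees with the public Newton fit."""
        X = default_cohort[["v65", "ahac", "acute_gi", "smoker"]].to_numpy(float)
        y = default_cohort["late_gi"].to_numpy(float)
        subsets = np.array([[0, 1], [1, 2], [0, 3]])
        _, beta, ok = _fit_subsets(X, y, subsets, maxiter=60, tol=1e-10)
        assert ok.all()
        names = ["v65", "ahac", "acute_gi", "smoker"]
        for row, cols in zip(beta, subsets):
            res = LogisticNTCP(y, X[:, cols], [names[c] for c in cols]).fit()
            np.testing.assert_allclose(row, res.params.to_numpy(), atol=1e-5)


def _planted_cohort(seed, n=100, beta=2.0, n_noise=4):
    rng = np.random.default_rng(seed)
    signal = rng.normal(size=n)
    df = pd.DataFrame({"signal": signal})
    for i in range(n_noise):
        df[f"noise{i}"] = rng.integers(0, 2, n).astype(float)
    df["late_gi"] = (rng.random(n) < expit(-0.3 + beta * signal)).astype(int)
    return df


class TestBootstrapSelect:
    def test_planted_signal_dominates_order_one(self):
        df = _planted_cohort(seed=10)
        pool = ["signal", "noise0", "noise1", "noise2", "noise3"]
        rep = bootstrap_select(df, pool, n_boot=200, max_order=1, seed=0)
        top = rep.model_frequencies[1][0]
        assert top[0] == ("signal",)
        assert top[1] > 0.9 * rep.n_valid[1]

    def test_null_pool_prefers_smallest_order(self):
        """With honest (out-of-bag) scoring on pure noise, adding covariates
        gives no Rs gain, so the plateau rule stops at order 1.  Within one
        cohort a noise covariate can win persistently through its fixed
        chance correlation, so the no-systematic-winner property is checked
        across independent cohorts: the top variable is cohort-specific."""
        pool = [f"n{i}" for i in range(5)]
        orders, winners = [], []
        for rep_seed in range(12):
            rng = np.random.default_rng(200 + rep_seed)
            n = 200
            df = pd.DataFrame({v: rng.normal(size=n) for v in pool})
            df["late_gi"] = rng.integers(0, 2, n)
            rep = bootstrap_select(df, pool, n_boot=50, max_order=2, seed=rep_seed, oob=True)
            orders.append(rep.chosen_order)
            winners.append(rep.model_frequencies[1][0][0])
        assert np.mean([o == 1 for o in orders]) >= 0.8
        assert len(set(winners)) >= 2

    def test_bit_stable_across_runs(self, default_cohort):
        pool = ["v65", "ahac", "acute_gi", "smoker", "diabetes"]
        a = bootstrap_select(default_cohort, pool, n_boot=60, max_order=2, seed=9)
        b = bootstrap_select(default_cohort, pool, n_boot=60, max_order=2, seed=9)
        assert a.model_frequencies == b.model_frequencies
        assert a.order_mean_rs == b.order_mean_rs
        assert a.chosen_model == b.chosen_model

    def test_frequency_counts_sum_to_valid_bootstraps(self, default_cohort):
        pool = ["v65", "ahac", "acute_gi", "smoker"]
        rep = bootstrap_select(default_cohort, pool, n_boot=80, max_order=2, seed=3)
        for order, entries in rep.model_frequencies.items():
            assert sum(c for _, c, _ in entries) == rep.n_valid[order]
        assert set(rep.chosen_model) <= set(rep.candidate_pool)

    def test_selection_frequency_increases_with_effect_size(self):
        freqs = []
        for beta in (0.2, 0.9, 2.5):
            df = _planted_cohort(seed=30, beta=beta)
            rep = bootstrap_select(
                df, ["signal", "noise0", "noise1", "noise2"], n_boot=100,
                max_order=1, seed=5,
            )
            by_name = {s: c for s, c, _ in rep.model_frequencies[1]}
            freqs.append(by_name[("signal",)])
        assert freqs[0] <= freqs[1] <= freqs[2]

    def test_model_one_structure_recovered(self):
        """Scaled replica: cohorts generated from the reference three-variable
        model rank {v65, ahac, acute_gi} first among order-3 subsets."""
        df = generate_cohort(CohortSpec(seed=101))
        pool = ["v65", "ahac", "acute_gi", "smoker", "diabetes", "t3"]
        rep = bootstrap_select(df, pool, n_boot=150, max_order=3, seed=2)
        assert rep.chosen_order == 3
        assert set(rep.model_frequencies[3][0][0]) == {"v65", "ahac", "acute_gi"}
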