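"""Stratified estimators, pruning, inference, and the balance diagnostic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import coarsecause as cc
from coarsecause.errors import ConfigError, EstimationImpossibleError, StrataError
from conftest import random_stratified_dataset


def _assignment(labels):
    return cc.StrataAssignment(np.asarray(labels), method="manual")


class TestPruneStrata:
    def test_single_arm_strata_dropped_with_reasons(self):
        labels = [1] * 4 + [2] * 3 + [3] * 4
        t = np.array([1, 1, 0, 0] + [1, 1, 1] + [0, 0, 0, 0])
        pruned = cc.prune_strata(_assignment(labels), t)
        assert pruned.retained == [1]
        assert dict(pruned.dropped) == {2: "no_control", 3: "no_treated"}
        assert pruned.n_used == 4

    def test_all_mixed_is_noop(self):
        labels = [1, 1, 2, 2]
        t = np.array([1, 0, 1, 0])
        pruned = cc.prune_strata(_assignment(labels), t)
        assert pruned.dropped == [] and pruned.n_used == 4

    def test_min_per_arm_threshold(self):
        labels = [1] * 6 + [2] * 4
        t = np.array([1, 0, 0, 0, 0, 0] + [1, 1, 0, 0])
        pruned = cc.prune_strata(_assignment(labels), t, min_per_arm=2)
        assert dict(pruned.dropped) == {1: "below_min_per_arm"}

    def test_nothing_retained_raises(self):
        labels = [1, 1, 2, 2]
        t = np.array([1, 1, 0, 0])
        with pytest.raises(EstimationImpossibleError):
            cc.prune_strata(_assignment(labels), t)


class TestAteEstimate:
    def test_toy_two_strata_hand_values(self, toy_dataset):
        dataset, assignment = toy_dataset
        est = cc.ate_estimate(dataset, cc.prune_strata(assignment, dataset.t))
        assert est.tau_hat == pytest.approx(2.5)
        assert est.var_hat == pytest.approx(1.0)
        assert est.se == pytest.approx(1.0)
        assert est.strata_table["weight"].sum() == pytest.approx(1.0)

    def test_single_stratum_is_two_sample_difference(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=40)
        t = np.r_[np.ones(15, int), np.zeros(25, int)]
        dataset = cc.Dataset(y=y, t=t, x=pd.DataFrame({"x": np.zeros(40)}))
        est = cc.ate_estimate(dataset, cc.prune_strata(_assignment([1] * 40), t))
        y1, y0 = y[t == 1], y[t == 0]
        assert est.tau_hat == pytest.approx(y1.mean() - y0.mean())
        assert est.var_hat == pytest.approx(
            y1.var(ddof=1) / 15 + y0.var(ddof=1) / 25
        )

    def test_constant_outcome_degenerate(self):
        y = np.full(8, 3.0)
        t = np.array([1, 0] * 4)
        dataset = cc.Dataset(y=y, t=t, x=pd.DataFrame({"x": np.zeros(8)}))
        est = cc.ate_estimate(dataset, cc.prune_strata(_assignment([1, 1, 2, 2] * 2), t))
        assert est.tau_hat == 0.0 and est.var_hat == 0.0
        assert est.p_value == 1.0 and est.ci == (0.0, 0.0)

    def test_singleton_arm_borrows_pooled_variance(self, caplog):
        y = np.array([1.0, 2, 3, 7, 4, 5, 6])
        t = np.array([1, 0, 0, 1, 1, 0, 0])
        labels = [1, 1, 1, 2, 2, 2, 2]
        dataset = cc.Dataset(y=y, t=t, x=pd.DataFrame({"x": np.zeros(7)}))
        with caplog.at_level("WARNING", logger="coarsecause"):
            est = cc.ate_estimate(dataset, cc.prune_strata(_assignment(labels), t))
        assert "min_per_arm=2" in caplog.text
        assert np.isfinite(est.var_hat) and est.var_hat > 0

    def test_unbiased_under_within_stratum_randomization(self):
        """With T randomized within strata independently of the outcome
        surface, the stratified estimator is unbiased: the replicate mean
        lands within 3 Monte-Carlo SEs of the constant truth."""
        rng = np.random.default_rng(0)
        tau_true = 1.5
        n, reps = 120, 2000
        labels = np.repeat([1, 2, 3, 4], n // 4)
        p_by_stratum = np.repeat([0.3, 0.5, 0.6, 0.4], n // 4)
        x = rng.normal(size=n) + labels  # outcome surface varies within strata
        assignment = _assignment(labels)
        estimates = np.empty(reps)
        for r in range(reps):
            t = rng.binomial(1, p_by_stratum)
            while t.sum() in (0, n):
                t = rng.binomial(1, p_by_stratum)
            y = x + tau_true * t + rng.normal(size=n)
            dataset = cc.Dataset(y=y, t=t, x=pd.DataFrame({"x": x}))
            try:
                pruned = cc.prune_strata(assignment, t)
            except EstimationImpossibleError:
                estimates[r] = np.nan
                continue
            estimates[r] = cc.ate_estimate(dataset, pruned).tau_hat
        estimates = estimates[np.isfinite(estimates)]
        mc_se = estimates.std(ddof=1) / np.sqrt(len(estimates))
        assert abs(estimates.mean() - tau_true) < 3 * mc_se


class TestEstimatingEquationOracle:
    def test_toy_equals_closed_form(self, toy_dataset):
        dataset, assignment = toy_dataset
        pruned = cc.prune_strata(assignment, dataset.t)
        root = cc.estimating_equation_root(dataset, pruned)
        assert root == pytest.approx(2.5, abs=1e-10)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_oracle_equivalence_random_data(self, seed):
        rng = np.random.default_rng(seed)
        dataset, assignment = random_stratified_dataset(rng)
        pruned = cc.prune_strata(assignment, dataset.t)
        est = cc.ate_estimate(dataset, pruned)
        root = cc.estimating_equation_root(dataset, pruned)
        assert abs(est.tau_hat - root) < 1e-10


class TestAttEstimate:
    def test_hand_computed_odds_weights(self):
        labels = [1] * 4 + [2] * 4
        t = np.array([1, 1, 1, 0] + [1, 0, 0, 0])
        y = np.arange(8, dtype=float)
        dataset = cc.Dataset(y=y, t=t, x=pd.DataFrame({"x": np.zeros(8)}))
        est = cc.att_estimate(dataset, cc.prune_strata(_assignment(labels), t))
        w = est.strata_table.set_index("stratum")["w_j"]
        assert w[1] == pytest.approx(3.0)
        assert w[2] == pytest.approx(1 / 3)

    def test_constant_prevalence_reduces_to_ate(self, toy_dataset):
        dataset, assignment = toy_dataset
        pruned = cc.prune_strata(assignment, dataset.t)
        att = cc.att_estimate(dataset, pruned)
        ate = cc.ate_estimate(dataset, pruned)
        assert att.tau_hat == pytest.approx(ate.tau_hat)
        assert att.var_hat == pytest.approx(ate.var_hat)
        assert np.allclose(att.strata_table["w_j"], 1.0)

    def test_single_stratum_att_equals_ate(self):
        rng = np.random.default_rng(8)
        y = rng.normal(size=20)
        t = np.r_[np.ones(8, int), np.zeros(12, int)]
        dataset = cc.Dataset(y=y, t=t, x=pd.DataFrame({"x": np.zeros(20)}))
        pruned = cc.prune_strata(_assignment([1] * 20), t)
        att = cc.att_estimate(dataset, pruned)
        assert np.allclose(att.strata_table["w_j"], 1.0)
        assert att.tau_hat == pytest.approx(cc.ate_estimate(dataset, pruned).tau_hat)

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_variance_nonnegative_weights_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        dataset, assignment = random_stratified_dataset(rng)
        pruned = cc.prune_strata(assignment, dataset.t)
        for fit in (cc.ate_estimate, cc.att_estimate):
            est = fit(dataset, pruned)
            assert est.var_hat >= 0
            assert est.strata_table["weight"].sum() == pytest.approx(1.0)
            assert est.ci[0] <= est.tau_hat <= est.ci[1]


class TestWaldInference:
    def test_reported_rf_risk_difference(self):
        z, p, _ = cc.wald_inference(-0.021, 0.014)
        assert z == pytest.approx(-1.5)
        assert p == pytest.approx(0.13, abs=0.005)

    def test_null_estimate(self):
        z, p, ci = cc.wald_inference(0.0, 2.0)
        assert z == 0.0 and p == 1.0
        assert ci[0] == pytest.approx(-ci[1])

    def test_quantile_identity(self):
        z, p, ci = cc.wald_inference(1.96, 1.0, alpha=0.05)
        assert p == pytest.approx(0.05, abs=1e-3)
        assert ci[0] == pytest.approx(0.0, abs=1e-3)

    def test_zero_se_degenerate(self):
        z, p, ci = cc.wald_inference(1.0, 0.0)
        assert p == 0.0 and ci == (1.0, 1.0)

    def test_negative_se_rejected(self):
        with pytest.raises(ConfigError):
            cc.wald_inference(1.0, -0.1)


class TestL1Imbalance:
    def test_perfect_balance(self):
        labels = [1, 1, 2, 2, 1, 1, 2, 2]
        t = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert cc.l1_imbalance(_assignment(labels), t) == 0.0

    def test_mutually_exclusive(self):
        labels = [1, 1, 1, 1, 2, 2, 2, 2]
        t = np.array([1, 1, 1, 1, 0, 0, 0, 0])
        assert cc.l1_imbalance(_assignment(labels), t) == 1.0

    def test_hand_value_half(self):
        # treated shares (0.75, 0.25), control shares (0.25, 0.75)
        labels = [1] * 4 + [2] * 4
        t = np.array([1, 1, 1, 0] + [1, 0, 0, 0])
        assert cc.l1_imbalance(_assignment(labels), t) == pytest.approx(0.5)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        labels = rng.integers(1, 6, size=n)
        t = rng.integers(0, 2, size=n)
        if t.sum() in (0, n):
            t[0] = 1 - t[0]
        val = cc.l1_imbalance(_assignment(labels), t)
        assert 0.0 <= val <= 1.0

    def test_empty_arm_rejected(self):
        with pytest.raises(EstimationImpossibleError):
            cc.l1_imbalance(_assignment([1, 1, 2, 2]), np.array([1, 1, 1, 1]))
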