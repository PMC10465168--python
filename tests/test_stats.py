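"""Regression, Wilcoxon scoring and elementary-effects screening."""

import itertools

import numpy as np
import pytest

from optoca1 import stats
from optoca1.stats import (EEFactorSpec, elementary_effects, lapicque_fit,
                           lapicque_strength_duration, ranked_relative_change,
                           threshold_regression, wilcoxon_excitability_scores,
                           wilcoxon_one_sided)


class TestLapicque:
    def test_exact_recovery(self):
        pd = np.logspace(-1, 3, 9)
        tac = lapicque_strength_duration(pd, 3.0, 40.0)
        tac0, tau, r2 = lapicque_fit(pd, tac)
        assert tac0 == pytest.approx(3.0, abs=1e-6)
        assert tau == pytest.approx(40.0, abs=1e-6)
        assert r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_median_within_5pct(self, rng):
        pd = np.logspace(-1, 3, 9)
        truth = lapicque_strength_duration(pd, 3.0, 40.0)
        est = []
        for _ in range(100):
            noisy = truth * (1 + 0.05 * rng.standard_normal(len(pd)))
            tac0, _, _ = lapicque_fit(pd, np.abs(noisy))
            est.append(tac0)
        assert abs(np.median(est) - 3.0) / 3.0 < 0.05

    def test_flat_asymptote(self):
        tac0, _, _ = lapicque_fit([1000.0, 2000.0, 4000.0], [3.0, 3.0, 3.0])
        assert tac0 == pytest.approx(3.0, rel=1e-6)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            lapicque_fit([1.0, 2.0], [1.0, 2.0])


class TestThresholdRegression:
    def test_exact_recovery_of_log_linear_law(self, rng):
        # generate exactly from the log-linear law with the coefficients
        # of a typical strength-duration analysis
        a_g, a_pd, c = -1.47, 0.53, 0.2
        g = 10 ** rng.uniform(-1, 1.5, 40)
        tac = 10 ** rng.uniform(-1, 1, 40)
        ith = 10 ** (a_g * np.log10(g) + a_pd * np.log10(tac) + c)
        est = threshold_regression(g, tac, ith)
        assert est[0] == pytest.approx(a_g, abs=1e-9)
        assert est[1] == pytest.approx(a_pd, abs=1e-9)
        assert est[2] == pytest.approx(c, abs=1e-9)
        assert est[3] == pytest.approx(1.0, abs=1e-9)

    def test_noise_lowers_adjusted_r2(self, rng):
        g = 10 ** rng.uniform(-1, 1.5, 60)
        tac = 10 ** rng.uniform(-1, 1, 60)
        ith = 10 ** (-1.0 * np.log10(g) + 0.5 * np.log10(tac))
        clean = threshold_regression(g, tac, ith)[3]
        noisy = threshold_regression(
            g, tac, ith * 10 ** (0.3 * rng.standard_normal(60)))[3]
        assert noisy < clean

    def test_single_gmax_level_rank_deficient(self):
        g = np.full(10, 2.0)
        tac = 10 ** np.linspace(-1, 1, 10)
        with pytest.raises(ValueError):
            threshold_regression(g, tac, tac)


def _exact_wilcoxon_greater(x, y):
    """Enumeration oracle: P(W+ >= observed) over all 2^n sign flips."""
    d = np.asarray(x, float) - np.asarray(y, float)
    d = d[d != 0]
    n = len(d)
    ranks = np.empty(n)
    order = np.argsort(np.abs(d))
    sorted_abs = np.abs(d)[order]
    # midranks for ties
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w_obs = ranks[d > 0].sum()
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w >= w_obs - 1e-12:
            count += 1
    return count / 2 ** n


class TestWilcoxon:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_exact_enumeration_for_small_n(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(6, 11)
        x = rng.normal(0.3, 1.0, n)
        y = rng.normal(0.0, 1.0, n)
        p_scipy = wilcoxon_one_sided(x, y)
        p_exact = _exact_wilcoxon_greater(x, y)
        assert p_scipy == pytest.approx(p_exact, abs=1e-10)

    def test_identical_vectors_score_zero(self):
        v = np.arange(10.0)
        scores, _ = wilcoxon_excitability_scores(
            {"a": v, "b": v.copy(), "c": v.copy()})
        assert all(s == 0.0 for s in scores.values())

    def test_location_shift_winner(self, rng):
        base = rng.normal(0, 1, 360)
        scores, pvals = wilcoxon_excitability_scores(
            {"hi": base + 5.0, "lo": base})
        assert scores["hi"] == 1.0
        assert scores["lo"] == 0.0
        assert pvals[("hi", "lo")] < 0.001

    def test_dominating_class_reaches_maximum_score(self, rng):
        base = rng.normal(0, 1, 100)
        vectors = {f"c{k}": base + k * 3.0 for k in range(4)}
        scores, _ = wilcoxon_excitability_scores(vectors)
        assert scores["c3"] == pytest.approx(3.0)  # n_classes - 1

    def test_smaller_is_better_orientation(self, rng):
        base = rng.normal(0, 1, 100)
        scores, _ = wilcoxon_excitability_scores(
            {"low": base - 4.0, "high": base}, larger_is_better=False)
        assert scores["low"] == 1.0

    def test_unpaired_inputs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_excitability_scores({"a": np.ones(5), "b": np.ones(6)})


class TestRankedRelativeChange:
    def test_constant_metric(self):
        changes, med = ranked_relative_change([2.0, 2.0, 2.0])
        assert np.all(changes == 0)
        assert med == 0.0

    def test_geometric_sequence(self):
        vals = 10.0 * 0.8 ** np.arange(6)
        changes, med = ranked_relative_change(vals)
        assert np.allclose(changes, -0.2)
        assert med == pytest.approx(-0.2)

    def test_order_dependence(self, rng):
        vals = rng.uniform(1, 10, 8)
        _, med1 = ranked_relative_change(vals)
        _, med2 = ranked_relative_change(vals[::-1])
        assert med1 != med2

    def test_too_short(self):
        with pytest.raises(ValueError):
            ranked_relative_change([1.0])


class TestElementaryEffects:
    def test_linear_model_has_zero_sigma(self):
        specs = [EEFactorSpec("u1", "uniform", (0.0, 1.0)),
                 EEFactorSpec("u2", "uniform", (0.0, 1.0)),
                 EEFactorSpec("u3", "uniform", (0.0, 1.0))]
        res = elementary_effects(lambda x: 2.0 * x[0], specs, r=8, seed=1)
        assert res.mu_star[0] == pytest.approx(2.0, abs=1e-9)
        assert res.sigma[0] == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(res.mu_star[1:], 0.0)
        assert res.rank[0] == 1

    def test_interaction_raises_sigma(self):
        specs = [EEFactorSpec("u1", "uniform", (0.0, 1.0)),
                 EEFactorSpec("u2", "uniform", (0.0, 1.0))]
        res = elementary_effects(lambda x: x[0] * x[1], specs, r=16, seed=2)
        assert res.sigma[0] > 0.01
        assert res.sigma[1] > 0.01

    def test_mu_star_bounds_mean(self, rng):
        specs = [EEFactorSpec("u1", "uniform", (0.0, 1.0)),
                 EEFactorSpec("u2", "uniform", (0.0, 1.0))]
        res = elementary_effects(lambda x: np.sin(6 * x[0]) + x[1] ** 2,
                                 specs, r=16, seed=3)
        assert np.all(res.mu_star >= np.abs(res.mu) - 1e-12)

    def test_recovers_known_importance_ordering(self):
        specs = [EEFactorSpec(f"u{j}", "uniform", (0.0, 1.0))
                 for j in range(3)]
        res = elementary_effects(
            lambda x: 10 * np.sin(x[0]) + 1.0 * x[1] + 0.1 * x[2],
            specs, r=16, seed=4)
        assert list(res.rank) == [1, 2, 3]

    def test_discrete_factor_steps_between_classes(self):
        specs = [EEFactorSpec("cls", "discrete", ("a", "b")),
                 EEFactorSpec("u", "uniform", (0.0, 1.0))]

        def model(x):
            return (10.0 if x[0] == "b" else 0.0) + x[1]

        res = elementary_effects(model, specs, r=8, seed=5)
        assert res.mu_star[0] > 1.0  # every step flips the class

    def test_normal_factor_truncation(self):
        spec = EEFactorSpec("mu_a", "normal", (0.42, 0.15))
        vals = [spec.transform(u) for u in np.linspace(1e-9, 1 - 1e-9, 101)]
        assert all(v > 0 for v in vals)  # 4-sigma truncation keeps physics
        assert np.median(vals) == pytest.approx(0.42, rel=0.01)

    def test_deterministic_given_seed(self):
        specs = [EEFactorSpec("u", "uniform", (0.0, 1.0)),
                 EEFactorSpec("v", "uniform", (0.0, 1.0))]
        f = lambda x: x[0] + 2 * x[1]  # noqa: E731
        r1 = elementary_effects(f, specs, r=8, seed=7)
        r2 = elementary_effects(f, specs, r=8, seed=7)
        assert np.array_equal(r1.effects, r2.effects)

    def test_model_failure_reported_with_point(self):
        specs = [EEFactorSpec("u", "uniform", (0.0, 1.0)),
                 EEFactorSpec("v", "uniform", (0.0, 1.0))]

        def bad(x):
            raise ZeroDivisionError

        with pytest.raises(RuntimeError, match="model failed"):
            elementary_effects(bad, specs, r=4, seed=0)

    def test_r_lower_bound(self):
        with pytest.raises(ValueError):
            elementary_effects(lambda x: 0.0,
                               [EEFactorSpec("u", "uniform", (0, 1))], r=1)


def test_two_step_pipeline_roundtrip(rng):
    # generate thresholds exactly from the two-step law and recover it
    pd = np.tile(np.logspace(-1, 3, 9), 5)
    g = np.repeat(10 ** np.linspace(-1, 1.5, 5), 9)
    tac = lapicque_strength_duration(pd, 3.0, 40.0)
    ith = 10 ** (-1.47 * np.log10(g) + 0.53 * np.log10(tac) + 0.2)
    fit = stats.fit_two_step(pd, g, tac, ith)
    assert fit.tac0 == pytest.approx(3.0, abs=1e-6)
    assert fit.tau_tac == pytest.approx(40.0, abs=1e-6)
    assert fit.a_g == pytest.approx(-1.47, abs=1e-6)
    assert fit.a_pd == pytest.approx(0.53, abs=1e-6)
    assert fit.r2_tot == pytest.approx(1.0, abs=1e-9)
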