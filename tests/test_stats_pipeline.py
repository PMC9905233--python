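"""Analysis pipeline: count/learning-curve/quality models, mediation, tests."""

import numpy as np
import pandas as pd
import pytest

from cohesim import (
    EmptyInputError,
    compare_groups,
    fit_exploration_quality,
    fit_learning_curve,
    fit_profitable_count_model,
    mediate,
)


def make_counts(rng, slope=0.05, sd=0.3, n_runs=40, n_iter=12, kind_shift=None):
    """Poisson counts with a run random intercept and known iteration slope."""
    rows = []
    b = rng.normal(0, sd, n_runs)
    for kind in ("none", "additive", "multiplicative"):
        shift = 0.0 if kind_shift is None else kind_shift.get(kind, 0.0)
        for r in range(n_runs):
            for t in range(1, n_iter + 1):
                lam = np.exp(0.3 + slope * t + shift * t + b[r])
                rows.append((r, t, kind, rng.poisson(lam)))
    return pd.DataFrame(rows, columns=["run", "iteration", "bonus_kind", "count"])


def make_learning(rng, slope=0.06, sd_p=0.4, sd_g=0.3, n_groups=6):
    rows = []
    for g in range(n_groups):
        bg = rng.normal(0, sd_g)
        for pl in range(6):
            bp = rng.normal(0, sd_p)
            for t in range(1, 31):
                p = 1 / (1 + np.exp(-(slope * t + bp + bg)))
                rows.append((f"g{g}", f"p{pl}", t, int(rng.random() < p)))
    return pd.DataFrame(rows, columns=["group", "player", "round", "profitable"])


class TestProfitableCountModel:
    def test_recovers_generating_slope(self, rng):
        res = fit_profitable_count_model(make_counts(rng, slope=0.05))
        lo, hi = res.ci95["iteration"]
        assert lo < 0.05 < hi

    def test_constant_counts_give_null_slope(self, rng):
        counts = make_counts(rng, slope=0.0)
        res = fit_profitable_count_model(counts)
        est = res.coefficients["iteration"]
        lo, hi = res.ci95["iteration"]
        se = (hi - lo) / (2 * 1.96)
        assert abs(est) < 2 * se

    def test_deviation_effects_sum_to_zero(self, rng):
        res = fit_profitable_count_model(
            make_counts(rng, kind_shift={"multiplicative": -0.04, "none": 0.02})
        )
        inter = [
            res.coefficients[f"bonus[{k}]:iteration"]
            for k in ("none", "additive", "multiplicative")
        ]
        assert sum(inter) == pytest.approx(0.0, abs=1e-10)
        assert res.coefficients["bonus[multiplicative]:iteration"] < 0
        assert res.coefficients["bonus[none]:iteration"] > 0

    def test_non_integer_counts_rejected(self):
        df = pd.DataFrame(
            {"run": [0, 0], "iteration": [1, 2], "bonus_kind": ["none"] * 2,
             "count": [1.5, 2.0]}
        )
        with pytest.raises(ValueError, match="integer"):
            fit_profitable_count_model(df)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            fit_profitable_count_model(pd.DataFrame({"run": [], "count": []}))


class TestLearningCurve:
    def test_recovers_generating_slope(self, rng):
        res = fit_learning_curve(make_learning(rng, slope=0.06))
        lo, hi = res.ci95["round"]
        assert lo < 0.06 < hi

    def test_immediate_ceiling_predicts_near_one(self, rng):
        df = make_learning(rng)
        df["profitable"] = 1  # everyone profitable from round 1
        res = fit_learning_curve(df)
        slope = res.coefficients["round"]
        for t in (1, 15, 30):
            prob = 1 / (1 + np.exp(-slope * t))
            assert prob >= 0.99

    def test_shuffled_rounds_null_slope(self, rng):
        # with an intercept absorbing the base rate, a permutation of the
        # round labels must leave no slope signal
        df = make_learning(rng, slope=0.08)
        df["round"] = rng.permutation(df["round"].to_numpy())
        res = fit_learning_curve(df, include_intercept=True)
        est = res.coefficients["round"]
        lo, hi = res.ci95["round"]
        se = (hi - lo) / (2 * 1.96)
        assert abs(est) < 2 * se

    def test_condition_interaction_terms_present(self, rng):
        df = make_learning(rng)
        df["condition"] = (df["group"].str[1:].astype(int) % 2).astype(float)
        res = fit_learning_curve(df, condition=True)
        assert {"Intercept", "round", "condition", "condition:round"} <= set(
            res.coefficients
        )

    def test_non_binary_outcome_rejected(self, rng):
        df = make_learning(rng)
        df.loc[0, "profitable"] = 2
        with pytest.raises(ValueError, match="binary"):
            fit_learning_curve(df)


class TestExplorationQuality:
    def test_linear_generator_keeps_quadratic_null(self, rng):
        rows = []
        for g in range(12):
            bg = rng.normal(0, 2.0)
            for pl in range(6):
                hcr = rng.integers(1, 25)
                score = 80 - 0.8 * hcr + bg + rng.normal(0, 3)
                rows.append((f"g{g}", hcr, score))
        df = pd.DataFrame(rows, columns=["group", "half_change_round", "choice_score"])
        res = fit_exploration_quality(df)
        assert res.p_values["half_change_round^2"] > 0.05
        assert res.fit_stats["lrt_chi2"] < 3.84
        assert res.fit_stats["linear_only_slope"] == pytest.approx(-0.8, abs=0.25)

    def test_u_shape_sign_recovered(self, rng):
        rows = []
        for g in range(12):
            bg = rng.normal(0, 2.0)
            for pl in range(6):
                hcr = rng.integers(1, 30)
                score = 60 - 3.0 * hcr + 0.1 * hcr**2 + bg + rng.normal(0, 3)
                rows.append((f"g{g}", hcr, score))
        df = pd.DataFrame(rows, columns=["group", "half_change_round", "choice_score"])
        res = fit_exploration_quality(df)
        assert res.coefficients["half_change_round^2"] > 0
        assert res.p_values["half_change_round^2"] < 0.05
        assert res.fit_stats["lrt_chi2"] > 3.84

    def test_constant_outcome_null_slopes(self, rng):
        df = pd.DataFrame(
            {
                "group": np.repeat([f"g{i}" for i in range(6)], 6),
                "half_change_round": np.tile(np.arange(1, 7), 6),
                "choice_score": 70.0,
            }
        )
        res = fit_exploration_quality(df)
        assert res.coefficients["half_change_round"] == pytest.approx(0.0, abs=1e-6)
        assert res.coefficients["half_change_round^2"] == pytest.approx(0.0, abs=1e-6)

    def test_single_group_warns_and_drops_random_effect(self, rng):
        df = pd.DataFrame(
            {
                "group": "g0",
                "half_change_round": rng.integers(1, 30, 40),
                "choice_score": rng.normal(70, 5, 40),
            }
        )
        with pytest.warns(UserWarning, match="group"):
            fit_exploration_quality(df)


class TestMediation:
    def test_decomposition_identity(self, rng):
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        m = 2.0 * x + rng.normal(0, 1, n)
        y = 1.5 * x + 0.8 * m + rng.normal(0, 1, n)
        res = mediate(x, m, y, n_boot=200, seed=1)
        assert res.total_effect == pytest.approx(
            res.direct_effect + res.indirect_effect, abs=1e-8
        )
        assert res.indirect_effect > 0

    def test_independent_mediator_zero_proportion(self, rng):
        n = 200
        x = rng.integers(0, 2, n).astype(float)
        m = rng.normal(0, 1, n)  # independent of x
        y = 2.0 * x + rng.normal(0, 1, n)
        res = mediate(x, m, y, n_boot=500, seed=2)
        assert res.proportion_mediated == 0.0
        assert res.indirect_ci[0] <= 0.0 <= res.indirect_ci[1]

    def test_full_mediation_dominates(self, rng):
        n = 300
        x = rng.integers(0, 2, n).astype(float)
        m = 2.0 * x + rng.normal(0, 0.5, n)
        y = 1.5 * m + rng.normal(0, 0.5, n)  # no direct path
        res = mediate(x, m, y, n_boot=300, seed=3)
        assert res.proportion_mediated > 0.8
        assert abs(res.direct_effect) < abs(res.indirect_effect)

    def test_constant_outcome_all_zero(self, rng):
        n = 100
        x = rng.integers(0, 2, n).astype(float)
        m = rng.normal(size=n)
        res = mediate(x, m, np.zeros(n), n_boot=200, seed=4)
        assert res.total_effect == pytest.approx(0.0, abs=1e-12)
        assert res.indirect_effect == pytest.approx(0.0, abs=1e-12)
        assert res.proportion_mediated == 0.0

    def test_small_bootstrap_refused(self, rng):
        with pytest.raises(ValueError, match="n_boot"):
            mediate([0, 1, 0], [1, 2, 3], [1, 2, 3], n_boot=50)


class TestCompareGroups:
    def test_identical_groups(self):
        a = np.arange(20.0)
        res = compare_groups(a, a.copy(), test="welch_t")
        assert res.p_value == pytest.approx(1.0)
        assert res.effect_size == pytest.approx(0.0)

    def test_welch_detects_unit_shift(self, rng):
        a = rng.normal(0, 1, 50)
        b = rng.normal(1, 1, 50)
        res = compare_groups(a, b, test="welch_t")
        assert res.p_value < 0.05
        assert res.effect_size < 0  # a below b

    def test_wilcoxon_ranksum(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(1.2, 1, 40)
        res = compare_groups(a, b, test="wilcoxon", alternative="less")
        assert res.p_value < 0.01

    def test_chi_square_independent_margins(self):
        table = np.outer([40, 60], [30, 70]) / 100.0 * 100
        res = compare_groups(table, test="chi_square")
        assert res.p_value > 0.9
        assert res.effect_size == pytest.approx(0.0, abs=1e-6)

    def test_empty_group_rejected(self):
        with pytest.raises(EmptyInputError):
            compare_groups([1.0], [1.0, 2.0], test="welch_t")
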