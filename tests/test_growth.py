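"""Growth stage: reverse standardization, per-individual OLS, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plsgrowth import (
    TimeCoding,
    aggregate_growth,
    fit_individual_growth,
    growth_confidence_interval,
    mean_se_from_components,
    reverse_standardize,
)
from plsgrowth.growth import (
    fit_growth_matrix,
    growth_fit_summary,
    implied_estimate_variance,
)
from plsgrowth.pls import disjoint_stage_scores
from plsgrowth.simulate import SimulationParams, model_spec_for, simulate_panel

LIN3 = TimeCoding.linear(3)


class TestTimeCoding:
    def test_linear_default(self):
        assert LIN3.lam == (0.0, 1.0, 2.0)
        assert LIN3.lambda_bar == 1.0
        assert LIN3.ss_lambda == 2.0
        assert LIN3.sum_sq == 5.0

    @pytest.mark.parametrize("lam", [(1.0, 2.0, 3.0), (0.0, 2.0, 1.0), (0.0, 1.0)])
    def test_invalid_codings_rejected(self, lam):
        with pytest.raises(ValueError):
            TimeCoding(lam)


class TestReverseStandardize:
    def test_restores_raw_composite_moments(self, default_sim):
        _, table, _, spec = default_sim
        scores = disjoint_stage_scores(table, spec)
        raw = reverse_standardize(scores, table, spec)
        for wave in spec.repeated_series:
            comp = table.values[spec.items_of(wave)].mean(axis=1)
            assert raw[wave].mean() == pytest.approx(comp.mean(), abs=1e-10)
            assert raw[wave].std(ddof=1) == pytest.approx(comp.std(ddof=1), abs=1e-10)

    def test_single_item_wave_returns_raw_column(self, rng):
        params = SimulationParams(
            n=40, repeated_loadings=(1.0,), predictors=(), predictor_corr=(),
            gamma_alpha=(), gamma_beta=(), seed=2,
        )
        table, _ = simulate_panel(params)
        spec = model_spec_for(params)
        scores = disjoint_stage_scores(table, spec)
        raw = reverse_standardize(scores, table, spec)
        for t, wave in enumerate(spec.repeated_series, start=1):
            np.testing.assert_allclose(
                raw[wave], table.values[f"SAT{t}_1"], atol=1e-10
            )

    def test_round_trip_recovers_scores(self, default_sim):
        _, table, _, spec = default_sim
        scores = disjoint_stage_scores(table, spec)
        raw = reverse_standardize(scores, table, spec)
        z = (raw - raw.mean()) / raw.std(ddof=1)
        for wave in spec.repeated_series:
            np.testing.assert_allclose(z[wave], scores.scores[wave], atol=1e-10)


class TestFitIndividualGrowth:
    @pytest.mark.parametrize(
        "y,expected",
        [
            ((5.0, 6.0, 7.0), (5.0, 1.0, 0.0, 1.0)),
            ((7.0, 7.5, 6.5), (7.25, -0.25, 0.375, 0.25)),
            ((4.0, 4.0, 4.0), (4.0, 0.0, 0.0, 1.0)),  # SST = 0 convention
        ],
        ids=["exact-line", "generic-series", "flat-series"],
    )
    def test_closed_form_examples(self, y, expected):
        got = fit_individual_growth(y, LIN3)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_matches_generic_least_squares_on_random_series(self, rng):
        # independent oracle: numpy polynomial fit, per series
        for _ in range(1000):
            T = int(rng.integers(3, 7))
            coding = TimeCoding.linear(T)
            y = rng.normal(scale=rng.uniform(0.1, 5), size=T) + rng.uniform(-10, 10)
            a, b, rv, r2 = fit_individual_growth(y, coding)
            slope, intercept = np.polyfit(coding.arr, y, 1)
            assert abs(a - intercept) < 1e-10
            assert abs(b - slope) < 1e-10
            resid = y - (intercept + slope * coding.arr)
            assert abs(rv - (resid @ resid) / (T - 2)) < 1e-10

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(-50, 50), min_size=3, max_size=3),
        st.floats(-20, 20),
    )
    def test_shift_moves_intercept_only(self, y, c):
        a0, b0, rv0, _ = fit_individual_growth(y, LIN3)
        a1, b1, rv1, _ = fit_individual_growth(np.asarray(y) + c, LIN3)
        assert a1 == pytest.approx(a0 + c, abs=1e-8)
        assert b1 == pytest.approx(b0, abs=1e-8)
        assert rv1 == pytest.approx(rv0, abs=1e-8)

    def test_reversed_waves_negate_slope_keep_residual_variance(self, rng):
        y = rng.normal(size=5)
        coding = TimeCoding.linear(5)
        a, b, rv, r2 = fit_individual_growth(y, coding)
        ar, br, rvr, r2r = fit_individual_growth(y[::-1], coding)
        assert br == pytest.approx(-b, abs=1e-12)
        assert rvr == pytest.approx(rv, abs=1e-12)
        assert r2r == pytest.approx(r2, abs=1e-12)

    def test_too_few_waves_rejected(self):
        with pytest.raises(ValueError):
            TimeCoding((0.0, 1.0))


class TestAggregateGrowth:
    def _individuals(self, alpha, beta, rv=None):
        n = len(alpha)
        return pd.DataFrame(
            {
                "alpha_hat": alpha,
                "beta_hat": beta,
                "resid_var": rv if rv is not None else np.zeros(n),
                "r2": np.ones(n),
            }
        )

    def test_means_are_simple_averages(self):
        g = aggregate_growth(self._individuals([5.0, 7.0, 9.0], [0.0, 1.0, 2.0]), LIN3)
        assert g.mu_alpha == pytest.approx(7.0)
        assert g.mu_beta == pytest.approx(1.0)
        assert g.individual["zeta_alpha"].tolist() == [-2.0, 0.0, 2.0]

    def test_zero_residual_variance_leaves_raw_variances(self):
        g = aggregate_growth(self._individuals([5.0, 7.0, 9.0], [0.0, 1.0, 2.0]), LIN3)
        assert g.psi_aa == pytest.approx(g.var_alpha_hat)
        assert g.psi_bb == pytest.approx(g.var_beta_hat)

    def test_negative_component_warned_not_truncated(self):
        rv = np.full(3, 10.0)  # huge occasion noise
        g = aggregate_growth(
            self._individuals([5.0, 5.1, 4.9], [0.0, 0.05, -0.05], rv), LIN3
        )
        assert g.psi_bb < 0
        assert any("psi_bb" in w for w in g.warnings)
        g_trunc = aggregate_growth(
            self._individuals([5.0, 5.1, 4.9], [0.0, 0.05, -0.05], rv),
            LIN3,
            truncate_negative=True,
        )
        assert g_trunc.psi_bb == 0.0

    def test_implied_se_reconstruction(self):
        # slope: sqrt((psi_bb + var_eps / S_ll) / N) with the three-wave
        # linear coding, using printed-scale component values
        se = mean_se_from_components(LIN3, 0.2530, 0.8327, 300, "beta")
        assert round(se, 4) == 0.0472
        # intercept: noise share var_eps * sum(lambda^2) / (T * S_ll);
        # the reconstruction from (rounded) component values sits exactly
        # on the rounding boundary, so compare at printed precision
        se_a = mean_se_from_components(LIN3, 0.8462, 0.8327, 300, "alpha")
        assert se_a == pytest.approx(0.0717, abs=1e-4)

    def test_implied_variance_is_inverse_of_correction(self, rng):
        coding = TimeCoding.linear(4)
        psi, ve = 0.4, 1.3
        va = implied_estimate_variance(coding, psi, ve, "alpha")
        noise = ve * coding.sum_sq / (coding.n_waves * coding.ss_lambda)
        assert va == pytest.approx(psi + noise, abs=1e-12)


class TestConfidenceInterval:
    def test_printed_value_arithmetic(self):
        lo, hi = growth_confidence_interval(7.5228, 0.0717, 0.95)
        assert round(lo, 4) == 7.3823
        se = mean_se_from_components(LIN3, 0.2530, 0.8327, 300, "beta")
        lo_b, hi_b = growth_confidence_interval(-0.2061, se, 0.95)
        assert round(lo_b, 4) == -0.2987
        assert round(hi_b, 4) == -0.1135

    def test_degenerate_se(self):
        assert growth_confidence_interval(1.5, 0.0) == (1.5, 1.5)

    def test_exact_z_slightly_narrower(self):
        lo_conv, _ = growth_confidence_interval(0.0, 1.0, 0.95, exact_z=False)
        lo_exact, _ = growth_confidence_interval(0.0, 1.0, 0.95, exact_z=True)
        assert lo_conv == -1.96
        assert lo_exact == pytest.approx(-1.959964, abs=1e-6)


class TestEstimatorCalibration:
    def test_recovery_of_variance_components(self, rng):
        # 200 direct draws of the growth layer (no measurement noise):
        # every estimator unbiased within 3 Monte-Carlo SEs, confirming
        # the sampling-noise corrections; also E[var(beta_hat)] =
        # psi_bb + sigma2 / S_ll.
        truth = dict(mu_a=7.5, mu_b=-0.2, psi_aa=0.85, psi_bb=0.25, s2=0.83)
        n, T, reps = 300, 3, 200
        coding = LIN3
        est = {k: [] for k in ("mu_a", "mu_b", "psi_aa", "psi_bb", "s2", "var_b")}
        local = np.random.default_rng(424242)
        for _ in range(reps):
            alpha = truth["mu_a"] + local.normal(0, np.sqrt(truth["psi_aa"]), n)
            beta = truth["mu_b"] + local.normal(0, np.sqrt(truth["psi_bb"]), n)
            Y = alpha[:, None] + np.outer(beta, coding.arr)
            Y = Y + local.normal(0, np.sqrt(truth["s2"]), (n, T))
            a, b, rv, r2 = fit_growth_matrix(Y, coding)
            g = aggregate_growth(
                pd.DataFrame(
                    {"alpha_hat": a, "beta_hat": b, "resid_var": rv, "r2": r2}
                ),
                coding,
            )
            est["mu_a"].append(g.mu_alpha)
            est["mu_b"].append(g.mu_beta)
            est["psi_aa"].append(g.psi_aa)
            est["psi_bb"].append(g.psi_bb)
            est["s2"].append(g.var_eps)
            est["var_b"].append(g.var_beta_hat)
        for key, target in [
            ("mu_a", truth["mu_a"]), ("mu_b", truth["mu_b"]),
            ("psi_aa", truth["psi_aa"]), ("psi_bb", truth["psi_bb"]),
            ("s2", truth["s2"]),
            ("var_b", truth["psi_bb"] + truth["s2"] / coding.ss_lambda),
        ]:
            vals = np.asarray(est[key])
            mc_se = vals.std(ddof=1) / np.sqrt(reps)
            assert abs(vals.mean() - target) < 3 * mc_se, key


class TestFitSummary:
    def test_exact_lines_give_unit_r2(self):
        ind = pd.DataFrame(
            {"alpha_hat": [1.0, 2.0], "beta_hat": [0.1, 0.2],
             "resid_var": [0.0, 0.0], "r2": [1.0, 1.0]}
        )
        s = growth_fit_summary(ind)
        assert s["r2"]["mean"] == 1.0

    def test_slope_heterogeneity_present_in_simulation(self, default_sim):
        # with psi_bb > 0 both improving and declining individuals occur
        _, table, _, spec = default_sim
        from plsgrowth.structural import run_stages

        _, _, growth, _ = run_stages(table, spec)
        betas = growth.individual["beta_hat"]
        assert (betas > 0).any() and (betas < 0).any()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            growth_fit_summary(pd.DataFrame(columns=["alpha_hat", "beta_hat", "r2"]))
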