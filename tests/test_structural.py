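"""Conditional structural model and bootstrap inference."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from plsgrowth import (
    Construct,
    EngineOptions,
    ModelSpec,
    StructuralPath,
    TimeCoding,
    aggregate_growth,
    check_collinearity,
    fit_conditional,
    summarize_significance,
)
from plsgrowth.pls import LatentScoreMatrix, estimate_pls
from plsgrowth.simulate import (
    PredictorDesign,
    SimulationParams,
    model_spec_for,
    simulate_panel,
)
from plsgrowth.structural import bootstrap_pipeline, run_stages

from conftest import exact_corr_data

LIN3 = TimeCoding.linear(3)


def _growth_from(alpha, beta):
    n = len(alpha)
    ind = pd.DataFrame(
        {"alpha_hat": alpha, "beta_hat": beta,
         "resid_var": np.zeros(n), "r2": np.ones(n)}
    )
    return aggregate_growth(ind, LIN3)


def _scores(df: pd.DataFrame) -> LatentScoreMatrix:
    z = (df - df.mean()) / df.std(ddof=1)
    return LatentScoreMatrix(z)


def _spec_with_paths(pred_names, targets=("intercept", "slope")):
    constructs = [
        Construct(f"W{t}", "single_item", (f"w{t}",)) for t in (1, 2, 3)
    ] + [Construct(p, "single_item", (f"{p.lower()}_item",)) for p in pred_names]
    return ModelSpec(
        constructs=tuple(constructs),
        repeated_series=("W1", "W2", "W3"),
        paths=tuple(StructuralPath(p, targets) for p in pred_names),
        options=EngineOptions(),
    )


class TestFitConditional:
    def test_perfect_predictor_recovers_outcome_sd(self, rng):
        alpha = rng.normal(7.5, 1.0, 200)
        beta = rng.normal(-0.2, 0.5, 200)
        scores = _scores(pd.DataFrame({"P": alpha}))
        res = fit_conditional(_growth_from(alpha, beta), scores, _spec_with_paths(["P"]))
        # standardized predictor identical to outcome: gamma = sd(outcome)
        assert res.paths.loc[("P", "intercept"), "estimate"] == pytest.approx(
            alpha.std(ddof=1), abs=1e-10
        )
        assert res.equations["intercept"]["r2"] == pytest.approx(1.0, abs=1e-12)

    def test_independent_predictor_near_zero(self, rng):
        n = 1000
        alpha = rng.normal(7.5, 1.0, n)
        beta = rng.normal(-0.2, 0.5, n)
        scores = _scores(pd.DataFrame({"P": rng.normal(size=n)}))
        res = fit_conditional(_growth_from(alpha, beta), scores, _spec_with_paths(["P"]))
        assert abs(res.paths.loc[("P", "intercept"), "estimate"]) < 0.1
        assert abs(res.paths.loc[("P", "slope"), "estimate"]) < 0.1
        assert res.equations["intercept"]["r2"] < 0.02
        assert res.equations["slope"]["r2"] < 0.02

    def test_no_predictors_reduces_to_unconditional_means(self, rng):
        alpha = rng.normal(7.5, 1.0, 50)
        beta = rng.normal(-0.2, 0.5, 50)
        spec = _spec_with_paths([])
        res = fit_conditional(_growth_from(alpha, beta), _scores(pd.DataFrame(index=range(50))), spec)
        assert res.paths.empty
        assert res.equations["intercept"]["intercept"] == pytest.approx(alpha.mean())
        assert res.equations["slope"]["intercept"] == pytest.approx(beta.mean())

    def test_orthogonal_predictors_match_simple_slopes(self, rng):
        n = 300
        X = exact_corr_data(np.eye(2), n, rng)
        alpha = 7.5 + 0.6 * X[:, 0] - 0.3 * X[:, 1] + rng.normal(0, 0.5, n)
        beta = rng.normal(-0.2, 0.3, n)
        scores = LatentScoreMatrix(pd.DataFrame(X, columns=["P1", "P2"]))
        res = fit_conditional(
            _growth_from(alpha, beta), scores, _spec_with_paths(["P1", "P2"])
        )
        for p in ("P1", "P2"):
            simple = np.linalg.lstsq(
                np.column_stack([np.ones(n), scores.scores[p]]), alpha, rcond=None
            )[0][1]
            assert res.paths.loc[(p, "intercept"), "estimate"] == pytest.approx(
                simple, abs=1e-10
            )

    def test_r2_invariant_to_affine_predictor_rescaling(self, rng):
        # predictors reach the regression as standardized scores, so any
        # raw-scale affine change is absorbed upstream; verify at the raw
        # item level through the full Stage-1 + Stage-3 chain
        params = SimulationParams(n=120, seed=4)
        table, _ = simulate_panel(params)
        spec = model_spec_for(params)
        _, _, _, res = run_stages(table, spec)
        rescaled = table.values.copy()
        rescaled["PSYCO_1"] = rescaled["PSYCO_1"] * 9.0 + 100.0
        from plsgrowth.panel import PanelTable

        _, _, _, res2 = run_stages(PanelTable(rescaled), spec)
        assert res.equations["intercept"]["r2"] == pytest.approx(
            res2.equations["intercept"]["r2"], abs=1e-10
        )

    def test_rank_deficient_predictors_rejected(self, rng):
        x = rng.normal(size=50)
        scores = LatentScoreMatrix(
            pd.DataFrame({"P1": (x - x.mean()) / x.std(ddof=1),
                          "P2": (x - x.mean()) / x.std(ddof=1)})
        )
        alpha = rng.normal(size=50)
        with pytest.raises(ValueError, match="collinear"):
            fit_conditional(
                _growth_from(alpha, alpha), scores, _spec_with_paths(["P1", "P2"])
            )


class TestCheckCollinearity:
    def test_orthogonal_predictors(self, rng):
        scores = LatentScoreMatrix(
            pd.DataFrame(exact_corr_data(np.eye(2), 100, rng), columns=["A", "B"])
        )
        rep = check_collinearity(scores)
        assert all(v == pytest.approx(1.0, abs=1e-9) for v in rep.vif.values())

    def test_correlated_predictors_critical(self, rng):
        R = np.array([[1.0, 0.95], [0.95, 1.0]])
        scores = LatentScoreMatrix(
            pd.DataFrame(exact_corr_data(R, 100, rng), columns=["A", "B"])
        )
        rep = check_collinearity(scores)
        assert rep.vif["A"] == pytest.approx(10.256, abs=1e-2)
        assert rep.bands["A"] == "critical"

    def test_single_predictor_trivially_ok(self, rng):
        scores = LatentScoreMatrix(pd.DataFrame({"A": rng.normal(size=30)}))
        rep = check_collinearity(scores)
        assert rep.vif["A"] == 1.0 and "trivially" in rep.note


@pytest.fixture(scope="module")
def small_sim():
    params = SimulationParams(
        n=150,
        repeated_loadings=(0.8, 0.85),
        predictors=(PredictorDesign("X1", (1.0,), True),),
        predictor_corr=((1.0,),),
        gamma_alpha=(0.3,),
        gamma_beta=(0.0,),
        seed=21,
    )
    table, _ = simulate_panel(params)
    spec = model_spec_for(params)
    outer, _ = estimate_pls(table, spec)
    return table, spec, outer


class TestBootstrap:

    def test_same_seed_bit_identical(self, small_sim):
        table, spec, outer = small_sim
        b1 = bootstrap_pipeline(table, spec, b=80, seed=5, reference=outer)
        b2 = bootstrap_pipeline(table, spec, b=80, seed=5, reference=outer)
        pd.testing.assert_frame_equal(b1.paths, b2.paths)
        pd.testing.assert_frame_equal(b1.weights, b2.weights)

    def test_single_replicate_flagged(self, small_sim):
        table, spec, outer = small_sim
        _, _, _, structural = run_stages(table, spec)
        boot = bootstrap_pipeline(table, spec, b=1, seed=5, reference=outer)
        res = summarize_significance(structural, boot)
        assert (res.paths["sig"] == "undefined").all()
        assert any("fewer than 2" in f for f in res.flags)

    def test_se_stable_between_moderate_and_large_b(self, small_sim):
        table, spec, outer = small_sim
        key = "X1->intercept"
        se_small, se_big = [], []
        for seed in range(10):
            bs = bootstrap_pipeline(table, spec, b=200, seed=seed, reference=outer)
            bb = bootstrap_pipeline(table, spec, b=1000, seed=seed, reference=outer)
            se_small.append(bs.paths[key].std(ddof=1))
            se_big.append(bb.paths[key].std(ddof=1))
        rel = abs(np.mean(se_small) - np.mean(se_big)) / np.mean(se_big)
        assert rel < 0.20

    def test_strong_effect_detected(self):
        # gamma = 0.5 at N = 300: the percentile CI should exclude zero in
        # essentially every replicate
        params = SimulationParams(
            n=300,
            repeated_loadings=(0.8, 0.85),
            predictors=(PredictorDesign("X1", (1.0,), True),),
            predictor_corr=((1.0,),),
            gamma_alpha=(0.5,),
            gamma_beta=(0.0,),
        )
        spec = model_spec_for(params)
        rng = np.random.default_rng(77)
        hits = 0
        outer_reps = 20
        for _ in range(outer_reps):
            s = int(rng.integers(2**31 - 1))
            table, _ = simulate_panel(replace(params, seed=s))
            outer, _, _, structural = run_stages(table, spec)
            boot = bootstrap_pipeline(table, spec, b=300, seed=s, reference=outer)
            res = summarize_significance(structural, boot)
            lo = res.paths.loc[("X1", "intercept"), "ci_lo"]
            hi = res.paths.loc[("X1", "intercept"), "ci_hi"]
            if not (lo <= 0 <= hi):
                hits += 1
        assert hits >= int(0.95 * outer_reps)

    def test_sign_patterns_of_significant_paths_match_truth(self):
        # moderate effects: whenever a path with |truth| >= 0.15 is called
        # significant, its sign must match the generating coefficient
        params = SimulationParams(n=300)
        spec = model_spec_for(params)
        truth = {}
        for i, name in enumerate(params.predictor_names):
            truth[f"{name}->intercept"] = params.gamma_alpha[i]
            truth[f"{name}->slope"] = params.gamma_beta[i]
        rng = np.random.default_rng(99)
        clean = 0
        outer_reps = 40
        for _ in range(outer_reps):
            s = int(rng.integers(2**31 - 1))
            table, _ = simulate_panel(replace(params, seed=s))
            outer, _, _, structural = run_stages(table, spec)
            boot = bootstrap_pipeline(table, spec, b=200, seed=s, reference=outer)
            res = summarize_significance(structural, boot)
            ok = True
            for (src, tgt), row in res.paths.iterrows():
                tv = truth[f"{src}->{tgt}"]
                if abs(tv) >= 0.15 and row["sig"] in ("p<0.05", "p<0.01"):
                    ok &= np.sign(row["estimate"]) == np.sign(tv)
            clean += ok
        assert clean >= int(0.90 * outer_reps)


class TestSummarizeSignificance:
    def test_symmetric_null_replicates_not_significant(self, rng):
        spec = _spec_with_paths(["P"])
        alpha = rng.normal(size=60)
        beta = rng.normal(size=60)
        scores = _scores(pd.DataFrame({"P": rng.normal(size=60)}))
        structural = fit_conditional(_growth_from(alpha, beta), scores, spec)
        from plsgrowth.structural import BootstrapDistribution

        reps = rng.normal(0, 0.05, 400)
        boot = BootstrapDistribution(
            paths=pd.DataFrame({
                "P->intercept": reps, "P->slope": rng.normal(0, 0.05, 400),
            }),
            weights=pd.DataFrame(), loadings=pd.DataFrame(), htmt=pd.DataFrame(),
            b_requested=400, seed=0, n_failed=0,
        )
        structural.paths.loc[("P", "intercept"), "estimate"] = 0.001
        res = summarize_significance(structural, boot)
        row = res.paths.loc[("P", "intercept")]
        assert row["ci_lo"] < 0 < row["ci_hi"]
        assert row["sig"] == "ns"
        # t is estimate over replicate SD, percentile CI from type-7 quantiles
        assert row["t"] == pytest.approx(0.001 / reps.std(ddof=1), rel=1e-9)
        assert row["ci_lo"] == pytest.approx(np.quantile(reps, 0.025), abs=1e-12)
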