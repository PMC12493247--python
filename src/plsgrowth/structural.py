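"""Stage 3: conditional growth model and bootstrap inference.

The per-individual intercepts and slopes from Stage 2 are regressed, by
OLS, on the saved latent scores of the time-invariant predictor
constructs. Because the sampling distribution of these path coefficients
is not derived analytically — the outcomes are themselves two stages of
estimation deep — significance is judged by a respondent-level bootstrap:
each replicate resamples rows with replacement and re-runs all three
stages (PLS weight estimation, score saving, reverse standardization,
growth fitting and the conditional regressions), so the replicate spread
reflects every source of estimation uncertainty.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assessment import CollinearityReport, _sig_level, htmt as _htmt_pair, vif
from .growth import GrowthEstimates, TimeCoding, aggregate_growth, fit_growth_matrix, reverse_standardize
from .model_spec import ModelSpec
from .panel import PanelTable
from .pls import (
    LatentScoreMatrix,
    OuterModel,
    PLSConvergenceError,
    estimate_pls,
    standardize,
)

__all__ = [
    "StructuralResults",
    "BootstrapDistribution",
    "fit_conditional",
    "check_collinearity",
    "run_stages",
    "bootstrap_pipeline",
    "summarize_significance",
]


@dataclass
class StructuralResults:
    """Path coefficients of the growth factors on the predictors.

    ``paths`` is indexed by (source construct, growth factor) and holds
    the point estimate in raw outcome units per standard deviation of the
    predictor score, alongside the fully standardized estimate; bootstrap
    columns (boot_se, t, ci_lo, ci_hi, sig) are filled by
    :func:`summarize_significance`.
    """

    paths: pd.DataFrame
    equations: dict[str, dict]  # per factor: intercept, r2, outcome_sd
    residuals: pd.DataFrame     # per-respondent zeta per factor
    collinearity: CollinearityReport | None
    level: float = 0.95
    flags: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _clean(v):
            if v is None or (isinstance(v, float) and not np.isfinite(v)):
                return None
            return float(v) if isinstance(v, (int, float, np.floating)) else v

        paths = {}
        for (src, tgt), row in self.paths.iterrows():
            paths[f"{src}->{tgt}"] = {k: _clean(v) for k, v in row.items()}
        return {
            "paths": paths,
            "equations": {
                t: {k: _clean(v) for k, v in eq.items()} for t, eq in self.equations.items()
            },
            "collinearity": self.collinearity.to_dict() if self.collinearity else None,
            "level": self.level,
            "flags": list(self.flags),
        }


def check_collinearity(predictors: LatentScoreMatrix) -> CollinearityReport:
    """VIF of the predictor scores (3 / 5 banding, shared with the
    formative-indicator check)."""
    return vif(predictors.scores)


def fit_conditional(
    growth: GrowthEstimates,
    predictors: LatentScoreMatrix,
    spec: ModelSpec,
) -> StructuralResults:
    """Point estimates of the conditional model.

    One OLS regression per growth factor, with an intercept; only
    predictors whose declared paths include that factor enter its
    equation. With no predictors for a factor, the equation reduces to
    the unconditional mean.
    """
    outcomes = {
        "intercept": growth.individual["alpha_hat"],
        "slope": growth.individual["beta_hat"],
    }
    by_factor: dict[str, list[str]] = {"intercept": [], "slope": []}
    for p in spec.paths:
        for t in p.targets:
            if p.source not in by_factor[t]:
                by_factor[t].append(p.source)

    rows = []
    equations: dict[str, dict] = {}
    residuals = {}
    for factor, y_series in outcomes.items():
        y = y_series.to_numpy(dtype=float)
        sd_y = float(y.std(ddof=1))
        sources = by_factor[factor]
        if not sources:
            equations[factor] = {
                "intercept": float(y.mean()),
                "r2": None,
                "outcome_sd": sd_y,
                "n_predictors": 0,
            }
            residuals[factor] = y - y.mean()
            continue
        if not set(sources) <= set(predictors.construct_names):
            missing = sorted(set(sources) - set(predictors.construct_names))
            raise ValueError(f"predictor score(s) missing: {missing}")
        X = predictors.scores[sources].to_numpy(dtype=float)
        n = X.shape[0]
        if len(y) != n:
            raise ValueError("growth estimates and predictor scores differ in length")
        design = np.column_stack([np.ones(n), X])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError(
                f"rank-deficient predictor block for {factor!r}: perfectly "
                f"collinear predictors among {sources}"
            )
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        fitted = design @ coef
        resid = y - fitted
        sst = float(((y - y.mean()) ** 2).sum())
        r2 = 1 - float((resid**2).sum()) / sst if sst > 0 else np.nan
        equations[factor] = {
            "intercept": float(coef[0]),
            "r2": float(r2),
            "outcome_sd": sd_y,
            "n_predictors": len(sources),
        }
        residuals[factor] = resid
        for s, g in zip(sources, coef[1:]):
            rows.append(
                dict(source=s, target=factor, estimate=float(g),
                     std_estimate=float(g / sd_y) if sd_y > 0 else np.nan)
            )

    paths = (
        pd.DataFrame(rows).set_index(["source", "target"])
        if rows
        else pd.DataFrame(columns=["estimate", "std_estimate"])
    )
    coll = (
        check_collinearity(predictors.subset(spec.predictor_names))
        if len(spec.predictor_names) >= 1
        else None
    )
    res_df = pd.DataFrame(residuals, index=growth.individual.index)
    return StructuralResults(
        paths=paths,
        equations=equations,
        residuals=res_df,
        collinearity=coll,
        level=spec.options.level,
    )


# ---------------------------------------------------------------------------
# single pass through the three stages (used by the bootstrap)
# ---------------------------------------------------------------------------

def _align_signs(outer: OuterModel, scores: LatentScoreMatrix, reference: OuterModel):
    """Flip replicate constructs whose weight vector points away from the
    original solution, removing the bootstrap's sign indeterminacy."""
    for name, fit in outer.constructs.items():
        ref = reference.constructs[name]
        if float(fit.weights @ ref.weights) < 0:
            fit.weights = -fit.weights
            fit.loadings = -fit.loadings
            scores.scores[name] = -scores.scores[name]


def run_stages(
    table: PanelTable,
    spec: ModelSpec,
    coding: TimeCoding | None = None,
    align_to: OuterModel | None = None,
) -> tuple[OuterModel, LatentScoreMatrix, GrowthEstimates, StructuralResults | None]:
    """One pass: PLS scores -> reverse standardization -> growth fits ->
    conditional structural model (skipped when the spec declares no paths).
    The table must already be imputed."""
    coding = coding or TimeCoding.linear(spec.n_waves)
    outer, scores = estimate_pls(table, spec)
    if align_to is not None:
        _align_signs(outer, scores, align_to)
    raw_scores = reverse_standardize(scores, table, spec)
    Y = raw_scores[list(spec.repeated_series)].to_numpy()
    alpha, beta, rv, r2 = fit_growth_matrix(Y, coding)
    individual = pd.DataFrame(
        {"alpha_hat": alpha, "beta_hat": beta, "resid_var": rv, "r2": r2},
        index=table.values.index,
    )
    growth = aggregate_growth(
        individual, coding, level=spec.options.level, exact_z=spec.options.z_exact
    )
    structural = fit_conditional(growth, scores, spec) if spec.paths else None
    return outer, scores, growth, structural


# ---------------------------------------------------------------------------
# bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapDistribution:
    """Replicate estimates from the respondent-level bootstrap.

    Each frame has one row per successful replicate. ``paths`` columns are
    "source->factor"; ``weights``/``loadings`` columns are
    "construct:item"; ``htmt`` columns are "A|B" construct pairs.
    """

    paths: pd.DataFrame
    weights: pd.DataFrame
    loadings: pd.DataFrame
    htmt: pd.DataFrame
    b_requested: int
    seed: int
    n_failed: int

    @property
    def b_successful(self) -> int:
        return len(self.paths)

    def to_dict(self) -> dict:
        return {
            "B": self.b_requested,
            "successful": self.b_successful,
            "failed": self.n_failed,
            "seed": self.seed,
        }


def bootstrap_pipeline(
    table: PanelTable,
    spec: ModelSpec,
    b: int | None = None,
    seed: int | None = None,
    reference: OuterModel | None = None,
    coding: TimeCoding | None = None,
    max_failure_rate: float = 0.10,
) -> BootstrapDistribution:
    """Respondent-level bootstrap of the full three-stage pipeline.

    Each replicate draws N respondents with replacement, re-estimates the
    PLS weights, aligns their signs to the original solution, and re-runs
    the growth and structural stages on the replicate's own reverse
    standardization. Besides the path coefficients, each replicate's outer
    weights, loadings and HTMT values are collected so that measurement
    quantities can be tested for significance from the same resamples.
    Non-convergent replicates are dropped and counted; more than
    ``max_failure_rate`` failures aborts with an error.

    The replicate loop runs on plain arrays (the same PLS core as
    :func:`~plsgrowth.pls.estimate_pls`), keeping B = 2000 on a few
    hundred respondents inexpensive.
    """
    from .pls import _pls_core, _spec_layout

    b = spec.options.bootstrap_b if b is None else b
    seed = spec.options.seed if seed is None else seed
    if b < 1:
        raise ValueError("bootstrap needs B >= 1")
    if table.has_missing:
        raise ValueError("impute the panel before bootstrapping")
    if reference is None:
        reference, _ = estimate_pls(table, spec)
    coding = coding or TimeCoding.linear(spec.n_waves)

    items = spec.all_items
    table.require_items(items)
    raw = table.values[items].to_numpy(dtype=float)
    n = raw.shape[0]
    blocks, modes, preds, succs = _spec_layout(spec)
    names = spec.construct_names
    name_idx = {nm: j for j, nm in enumerate(names)}
    ref_W = [reference.constructs[nm].weights for nm in names]
    scheme, tol, max_iter = spec.options.scheme, spec.options.tol, spec.options.max_iter

    wave_idx = [name_idx[w] for w in spec.repeated_series]
    lam = coding.arr
    lbar, sll = coding.lambda_bar, coding.ss_lambda

    # structural design: per growth factor, predictor construct indices
    by_factor: dict[str, list[int]] = {"intercept": [], "slope": []}
    for p in spec.paths:
        for t in p.targets:
            j = name_idx[p.source]
            if j not in by_factor[t]:
                by_factor[t].append(j)
    path_labels = [
        f"{names[j]}->{factor}"
        for factor in ("intercept", "slope")
        for j in by_factor[factor]
    ]

    item_labels = [
        f"{c.name}:{it}" for c in spec.constructs for it in c.items
    ]
    multi = [
        (c.name, blocks[name_idx[c.name]])
        for c in spec.constructs
        if c.mode == "reflective" and len(c.items) >= 2
    ]
    pair_labels = [
        f"{a}|{bn}" for i, (a, _) in enumerate(multi) for (bn, _) in multi[i + 1:]
    ]

    rng = np.random.default_rng(seed)
    path_vals = np.full((b, len(path_labels)), np.nan)
    w_vals = np.full((b, len(item_labels)), np.nan)
    l_vals = np.full((b, len(item_labels)), np.nan)
    h_vals = np.full((b, len(pair_labels)), np.nan)
    ok = np.zeros(b, dtype=bool)

    for r in range(b):
        idx = rng.integers(0, n, size=n)
        R = raw[idx]
        try:
            mu = R.mean(axis=0)
            sd = R.std(axis=0, ddof=1)
            if (sd == 0).any():
                raise ValueError("constant item column in replicate")
            X = (R - mu) / sd
            W, Y, _, _ = _pls_core(
                X, blocks, modes, preds, succs, scheme, tol, max_iter, names
            )
            for j, blk in enumerate(blocks):
                if float(W[j] @ ref_W[j]) < 0:
                    W[j] = -W[j]
                    Y[:, j] = -Y[:, j]
            # reverse standardization from the replicate's own composites
            Yw = np.empty((n, len(wave_idx)))
            for t, j in enumerate(wave_idx):
                comp = R[:, blocks[j]].mean(axis=1)
                csd = comp.std(ddof=1)
                if csd == 0:
                    raise ValueError("zero-variance composite in replicate")
                Yw[:, t] = Y[:, j] * csd + comp.mean()
            ybar = Yw.mean(axis=1)
            beta = ((lam - lbar) * (Yw - ybar[:, None])).sum(axis=1) / sll
            alpha = ybar - beta * lbar
            outcomes = {"intercept": alpha, "slope": beta}
            gam = []
            for factor in ("intercept", "slope"):
                srcs = by_factor[factor]
                if not srcs:
                    continue
                D = np.column_stack([np.ones(n), Y[:, srcs]])
                coef = np.linalg.solve(D.T @ D, D.T @ outcomes[factor])
                gam.extend(coef[1:])
        except (PLSConvergenceError, ValueError, np.linalg.LinAlgError):
            continue
        ok[r] = True
        if gam:
            path_vals[r] = gam
        w_vals[r] = np.concatenate(W)
        l_vals[r] = np.concatenate(
            [X[:, blk].T @ Y[:, j] / (n - 1) for j, blk in enumerate(blocks)]
        )
        if pair_labels:
            Ci = X.T @ X / (n - 1)
            col = 0
            for i, (a, sa) in enumerate(multi):
                for bn, sb in multi[i + 1:]:
                    v = _htmt_pair(Ci[sa, sa], Ci[sb, sb], Ci[sa, sb])
                    h_vals[r, col] = np.nan if v is None else v
                    col += 1

    n_failed = int(b - ok.sum())
    if n_failed > max_failure_rate * b:
        raise RuntimeError(
            f"{n_failed}/{b} bootstrap replicates failed to converge; "
            "inspect the data or loosen the convergence settings"
        )
    return BootstrapDistribution(
        paths=pd.DataFrame(path_vals[ok], columns=path_labels),
        weights=pd.DataFrame(w_vals[ok], columns=item_labels),
        loadings=pd.DataFrame(l_vals[ok], columns=item_labels),
        htmt=pd.DataFrame(h_vals[ok], columns=pair_labels),
        b_requested=b,
        seed=seed,
        n_failed=n_failed,
    )


def summarize_significance(
    structural: StructuralResults,
    boot: BootstrapDistribution,
    level: float | None = None,
) -> StructuralResults:
    """Attach bootstrap inference to the structural point estimates.

    SE is the replicate standard deviation (N-1 denominator); t is the
    point estimate over that SE, starred at the two-tailed normal cutoffs
    1.645 / 1.960 / 2.576; the CI holds the empirical percentile
    quantiles (linear, type-7 interpolation) of the replicates.
    """
    level = structural.level if level is None else level
    if boot.b_successful < 2:
        structural.flags.append(
            "bootstrap SE undefined: fewer than 2 successful replicates"
        )
        for col in ("boot_se", "t", "ci_lo", "ci_hi"):
            structural.paths[col] = np.nan
        structural.paths["sig"] = "undefined"
        return structural

    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    se_col, t_col, lo_col, hi_col, sig_col = [], [], [], [], []
    for (src, tgt), row in structural.paths.iterrows():
        key = f"{src}->{tgt}"
        reps = boot.paths[key].dropna().to_numpy()
        se = float(reps.std(ddof=1))
        est = float(row["estimate"])
        if se == 0:
            t = np.nan
            sig = "undefined"
            structural.flags.append(f"path {key}: all replicates identical, SE = 0")
        else:
            t = est / se
            sig = _sig_level(t) or "ns"
        se_col.append(se)
        t_col.append(t)
        lo_col.append(float(np.quantile(reps, lo_q)))
        hi_col.append(float(np.quantile(reps, hi_q)))
        sig_col.append(sig)
    structural.paths["boot_se"] = se_col
    structural.paths["t"] = t_col
    structural.paths["ci_lo"] = lo_col
    structural.paths["ci_hi"] = hi_col
    structural.paths["sig"] = sig_col
    structural.level = level
    return structural
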