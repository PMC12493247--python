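# Methods

This note documents the statistical procedures implemented in
`plsgrowth`, the defaults and numerical choices, what the synthetic-data
generator does and does not emulate, and the known limitations.

## Model

For respondent i = 1..N observed at waves t = 1..T, the repeated latent
outcome follows a linear trajectory

    y_it = α_i + λ_t β_i + ε_it,        ε_it iid, E ε = 0, var ε = σ²

with fixed time codes λ_t = t − 1 (λ_1 = 0 anchors the intercept at the
first wave; codes must be strictly increasing but need not be integers).
The growth factors are conditioned on time-invariant latent predictors:

    α_i = μ_α + γ_α′ x_i + ζ_αi,    β_i = μ_β + γ_β′ x_i + ζ_βi

Neither y nor x is observed directly: each is measured by survey items,
reflectively (items caused by the construct) or formatively (items compose
the construct), with one set of outcome items per wave.

Estimation is composite-based, not covariance-based: no distributional
assumption is imposed on the items, and inference is non-parametric
(respondent-level bootstrap). The price is that latent scores are
composites, so coefficients are attenuated relative to an error-free
latent metric when indicator reliability is modest; the measurement stage
exists precisely to quantify that reliability first.

## Stage 1: PLS estimation and measurement assessment

Items are standardized (mean 0, SD 1, N−1 denominator throughout the
package). Outer weights start at equal values scaled to a unit-variance
composite and iterate: inner proxies combine neighbouring constructs'
scores under the chosen scheme (path weighting by default — regression
coefficients toward predecessors, correlations toward successors; centroid
and factorial selectable), then Mode A (correlation) weights update
reflective blocks and Mode B (regression) weights update formative blocks,
each rescaled to a unit-variance composite. Convergence is declared when
the largest absolute weight change falls below 1e−7 (at most 300
iterations; non-convergence raises, and bootstrap replicates that fail to
converge are dropped and counted). Sign indeterminacy is resolved per
construct by making the sum of indicator loadings positive; bootstrap
replicates are additionally aligned to the original weight vector.

The estimation graph links every declared predictor construct to every
wave instance of the repeated construct; wave constructs are not linked to
each other. A construct with no structural neighbours uses its own score
as inner proxy (the update then converges toward the block's first
principal axis).

Assessment follows the conventional decision sequence, with inclusive
comparisons exactly as the thresholds are printed:

| metric | definition | verdict |
|---|---|---|
| indicator loading | cor(item, own score) | fail < 0.708 |
| Cronbach's α | k/(k−1)·(1 − Σs²_i/s²_total) | fail below 0.70 (0.60 in exploratory mode), warn above 0.95 |
| ρ_A | Dijkstra–Henseler, (w′w)²·w′(S−diag S)w / w′(ww′−diag ww′)w with w′Sw = 1 | same band |
| ρ_c | (Σℓ)² / ((Σℓ)² + Σ(1−ℓ²)) | same band |
| AVE | mean ℓ² | fail < 0.50 |
| HTMT | mean |heterotrait r| / √(product of mean within-construct |r|) | fail at ≥ 0.90 (or 0.85 if the user declares constructs conceptually different) |
| VIF | 1/(1−R²_j) | ok < 3, uncritical 3–5, critical ≥ 5 |
| redundancy | cor(formative score, global measure) | fail < 0.708 |

HTMT uses absolute correlations; a pair whose *signed* within-construct
mean correlation is non-positive has no meaningful monotrait reliability
and is reported as undefined rather than given a number. Single-item
constructs are excluded from HTMT (no monotrait correlations exist) and
report α/ρ_A/ρ_c as absent rather than 1. When a bootstrap has run, each
HTMT value also carries its percentile upper bound at the confidence
level, so "significantly below the threshold" can be read directly; the
similarity classification that selects 0.85 vs 0.90 is user-declared
(default 0.90) because conceptual similarity is not computable from data.
Formative indicator weights get bootstrap t values (normal cutoffs
1.645/1.960/2.576, two-tailed) and percentile CIs; a non-significant
weight is still flagged relevant when its loading is ≥ 0.50 and itself
significant.

## Stage 2: growth estimation

The saved standardized scores of the wave constructs are mapped back to
the survey scale: score × SD + mean of the observed raw composite, where
the composite is the unweighted mean of that construct's raw items at that
wave (the natural reading of "observed construct values"; for a single
indicator this inverts standardization exactly). Per-individual OLS then
uses the closed forms above; var(ε_i) divides by T − 2, which is why the
design requires at least three waves. R²_i is reported per respondent,
with the convention R² = 1 for a perfectly fitted flat series (SST = 0).

Aggregation: μ̂ are means; var(ε) is the mean of var(ε_i); ψ̂_αα and ψ̂_ββ
subtract the model-implied OLS sampling noise — var(ε)·Σλ²/(T·S_λλ) for
intercepts, var(ε)/S_λλ for slopes, S_λλ = Σ(λ_t−λ̄)² — from the raw
N−1 variances of the individual estimates. These corrections make the
components estimates of *true* between-person variance: simulation
confirms E[var(β̂)] = ψ_ββ + σ²/S_λλ and unbiasedness of the corrected
estimators (see the recovery tests). A corrected component can come out
negative when true heterogeneity is near zero; it is reported as-is with a
warning (an optional switch truncates at zero) because silently clipping
hides the information that the data cannot support individual-difference
claims.

Standard errors of the means are √(var(α̂)/N) and √(var(β̂)/N) — the
*uncorrected* variances, since the sampling noise of the individual
estimates genuinely contributes to the uncertainty of the mean.
Confidence intervals use mean ± z·SE with the conventional two-decimal
z = 1.96 at the 95% level (full-precision 1.959964 by option); the
two-decimal convention is what reproduces published tables of this kind
digit-for-digit.

## Stage 3: conditional model and bootstrap

Each growth factor regresses (OLS, with intercept) on the standardized
predictor scores named by its declared paths; outcomes stay on the raw
survey scale, so a coefficient reads "scale points (per wave) per SD of
the predictor"; fully standardized coefficients are reported alongside.
Predictor collinearity is checked by VIF before inference. With no
declared paths the stage reduces to the unconditional means and is
reported as absent.

Inference bootstraps *respondents*: each of B replicates (default 2000,
default seed 123) resamples N rows with replacement and re-runs PLS weight
estimation, score saving, reverse standardization on the replicate's own
composite moments, growth fitting and the conditional regressions. SE is
the replicate SD (N−1), t = estimate/SE against normal cutoffs, CIs are
empirical percentile (type-7) quantiles. All randomness flows from the
single user seed; identical seeds give bit-identical JSON reports.

A caveat established while validating calibration: if the *entire* inner
model is null (no predictor has any real effect), Mode-A outer weights of
multi-item constructs are unidentified — the inner proxy is noise, and the
weight update capitalizes on chance item–predictor correlations, inflating
type-I error of path tests (≈9% at nominal 5% in our experiments). This
is a property of the PLS weighting principle, not of the bootstrap; with
any real signal present in the inner model (the realistic applied
setting), null paths reject at ≈5.5%. Interpret significance of isolated
paths in models with *no* supported path with caution.

## Synthetic data generator

`simulate_panel` draws latent predictors from a correlated multivariate
normal, growth factors from the conditional model with bivariate-normal
disturbances Ψ, occasion residuals N(0, σ²) (or a variance-matched shifted
lognormal to exercise the distribution-free claim), and congeneric
indicators: loading × standardized true score + √(1−ℓ²) × noise. Wave
indicators are anchored to the *population* wave mean and SD (closed form
from the growth parameters), so growth is visible in indicator means
across waves while respondents remain iid draws — anchoring at realized
sample moments would couple rows and distort resampling inference.
Predictor indicators sit on a survey-like scale (mean 7.5, SD 1.2), which
is immaterial downstream because Stage 1 standardizes.

Defaults emulate a three-wave satisfaction panel: N = 300, μ_α = 7.52,
μ_β = −0.21, ψ_αα = 0.85, ψ_ββ = 0.25, ψ_αβ = 0, σ² = 0.83; three wave
items with loadings (0.75, 0.80, 0.85); predictors PSYCO (3 items), SOC
(2 items) and single-item Income with correlation 0.5 between the
well-being constructs and ≈0 with income; effects γ_α = (0.4, 0.2, 0.1),
γ_β = (−0.1, 0.15, 0) — psychological well-being raising the start and
steepening the decline, social well-being raising both, income touching
only the start. With ℓ = 1 and σ² = 0 the generator is exactly invertible:
Stage-1 scores equal standardized true scores and the pipeline recovers
every (α_i, β_i) to machine precision, which the tests exploit as an
end-to-end oracle.

What the generator does **not** emulate: attrition and panel nonresponse
beyond missing-completely-at-random cells, sampling weights, item-level
floor/ceiling effects of discrete Likert scales (indicators are
continuous), wave-specific measurement non-invariance, and time-varying
covariates. Passing tests therefore demonstrate correctness of the
estimators under the model's own assumptions, not robustness to those
real-data complications.

## Numerical and design choices

- Missing cells are mean-replaced per item *before* standardization;
  observed column means are preserved exactly. Imputation happens once;
  bootstrap replicates resample the imputed table.
- All standard deviations and variances use the N−1 denominator.
- Degenerate inputs raise informative errors: constant items, formative
  blocks with singular covariance, rank-deficient predictor sets,
  T < 3, fully missing columns, fewer than 3 respondents.
- Simulation sizes in the test suite (replicate counts, B per replicate)
  are chosen so each study's Monte-Carlo error is small relative to the
  band being checked while the whole suite stays in the minutes range;
  the calibration study uses a two-item wave design with one signal and
  one inert predictor, the recovery study uses the exactly invertible
  noiseless configuration to isolate the growth-stage estimators from
  measurement attenuation.

## Limitations

Linear trajectories only — no free-loading, quadratic or piecewise growth;
no time-varying covariates; no repeated-indicators or embedded two-stage
higher-order variants; no consistent-PLS disattenuation (coefficients are
composite-metric); no Fornell–Larcker or cross-loading tables (HTMT is the
discriminant criterion); model fit beyond per-equation R² is not assessed.
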