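"""Stage 2: per-individual linear growth estimation and its aggregation.

Each respondent's repeated latent scores (mapped back to the raw construct
scale) are regressed on fixed, linear time codes lambda_t = t - 1 by
ordinary least squares, giving an intercept alpha_i (initial status) and a
slope beta_i (rate of change per wave). Group-level parameters follow by
aggregation:

* mean intercept / slope: sample means of the individual estimates;
* residual variance var(eps): mean of the per-individual residual
  variances, each on T - 2 degrees of freedom;
* intercept / slope variance components psi_aa, psi_bb: the raw variances
  of the individual estimates minus the OLS sampling-noise contribution —
  var(eps) * sum(lambda^2) / (T * S_ll) for the intercept and
  var(eps) / S_ll for the slope, with S_ll = sum((lambda - mean lambda)^2).

The sampling-noise correction matters because each alpha_i, beta_i is
estimated from only T points: their raw dispersion overstates true
between-person heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model_spec import ModelSpec
from .panel import PanelTable
from .pls import LatentScoreMatrix

__all__ = [
    "TimeCoding",
    "GrowthEstimates",
    "reverse_standardize",
    "fit_individual_growth",
    "fit_growth_matrix",
    "aggregate_growth",
    "implied_estimate_variance",
    "mean_se_from_components",
    "growth_confidence_interval",
    "growth_fit_summary",
]


@dataclass(frozen=True)
class TimeCoding:
    """Fixed time scores lambda_t for the linear trajectory.

    The default, equally spaced coding is lambda_t = t - 1, anchoring the
    intercept at the first wave. The first code must be 0 and the codes
    strictly increasing.
    """

    lam: tuple[float, ...]

    def __post_init__(self):
        lam = np.asarray(self.lam, dtype=float)
        if lam.size < 3:
            raise ValueError("time coding needs at least 3 waves")
        if lam[0] != 0:
            raise ValueError("first time code must be 0 (intercept = wave-1 status)")
        if not np.all(np.diff(lam) > 0):
            raise ValueError("time codes must be strictly increasing")

    @classmethod
    def linear(cls, n_waves: int) -> "TimeCoding":
        return cls(tuple(float(t) for t in range(n_waves)))

    @property
    def arr(self) -> np.ndarray:
        return np.asarray(self.lam, dtype=float)

    @property
    def n_waves(self) -> int:
        return len(self.lam)

    @property
    def lambda_bar(self) -> float:
        return float(self.arr.mean())

    @property
    def ss_lambda(self) -> float:
        """Centred sum of squares sum((lambda - mean lambda)^2)."""
        return float(((self.arr - self.lambda_bar) ** 2).sum())

    @property
    def sum_sq(self) -> float:
        return float((self.arr**2).sum())


def reverse_standardize(
    scores: LatentScoreMatrix, table: PanelTable, spec: ModelSpec
) -> pd.DataFrame:
    """Map standardized wave scores back to the raw construct scale.

    For each wave construct the standardized latent score is multiplied by
    the standard deviation of, and shifted by the mean of, the observed
    raw composite — here the unweighted mean of the construct's raw items
    at that wave. The output therefore carries the construct's original
    units, so intercepts and slopes are interpretable on the survey scale.
    """
    out = {}
    for name in spec.repeated_series:
        items = spec.items_of(name)
        table.require_items(items)
        composite = table.values[items].mean(axis=1)
        mu, sd = float(composite.mean()), float(composite.std(ddof=1))
        if sd == 0:
            raise ValueError(f"raw composite of {name!r} has zero standard deviation")
        out[name] = scores.scores[name] * sd + mu
    return pd.DataFrame(out, index=scores.scores.index)


def fit_individual_growth(
    y, coding: TimeCoding
) -> tuple[float, float, float, float]:
    """Closed-form OLS line through one individual's series.

    Returns (alpha_hat, beta_hat, resid_var, r2) where resid_var is the
    residual sum of squares on T - 2 degrees of freedom and r2 is the
    usual coefficient of determination (set to 1.0 for a perfectly flat,
    perfectly fitted series where the total sum of squares is zero).
    """
    y = np.asarray(y, dtype=float)
    lam = coding.arr
    if y.shape[-1] != lam.size:
        raise ValueError("series length does not match time coding")
    a, b, rv, r2 = fit_growth_matrix(y.reshape(1, -1), coding)
    return float(a[0]), float(b[0]), float(rv[0]), float(r2[0])


def fit_growth_matrix(
    Y: np.ndarray, coding: TimeCoding
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised per-row OLS growth fit for an N x T outcome matrix."""
    Y = np.asarray(Y, dtype=float)
    lam = coding.arr
    T = lam.size
    if Y.ndim != 2 or Y.shape[1] != T:
        raise ValueError(f"expected an N x {T} matrix")
    if not np.isfinite(Y).all():
        raise ValueError("non-finite outcome values")
    lbar = coding.lambda_bar
    sll = coding.ss_lambda
    ybar = Y.mean(axis=1)
    beta = ((lam - lbar) * (Y - ybar[:, None])).sum(axis=1) / sll
    alpha = ybar - beta * lbar
    fitted = alpha[:, None] + np.outer(beta, lam)
    resid = Y - fitted
    sse = (resid**2).sum(axis=1)
    resid_var = sse / (T - 2)
    sst = ((Y - ybar[:, None]) ** 2).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - sse / sst
    r2 = np.where(sst == 0, 1.0, r2)  # flat, exactly fitted series
    return alpha, beta, resid_var, r2


@dataclass
class GrowthEstimates:
    """Individual and group-level growth parameters."""

    individual: pd.DataFrame  # alpha_hat, beta_hat, resid_var, r2, zeta_alpha, zeta_beta
    coding: TimeCoding
    mu_alpha: float
    mu_beta: float
    var_eps: float
    psi_aa: float
    psi_bb: float
    var_alpha_hat: float  # raw (uncorrected) variance of the alpha_i estimates
    var_beta_hat: float
    se_mu_alpha: float
    se_mu_beta: float
    ci_mu_alpha: tuple[float, float]
    ci_mu_beta: tuple[float, float]
    level: float
    warnings: list[str] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.individual)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "lambda": list(self.coding.lam),
            "mu_alpha": float(self.mu_alpha),
            "mu_beta": float(self.mu_beta),
            "var_eps": float(self.var_eps),
            "psi_aa": float(self.psi_aa),
            "psi_bb": float(self.psi_bb),
            "var_alpha_hat": float(self.var_alpha_hat),
            "var_beta_hat": float(self.var_beta_hat),
            "se_mu_alpha": float(self.se_mu_alpha),
            "se_mu_beta": float(self.se_mu_beta),
            "ci_mu_alpha": [float(v) for v in self.ci_mu_alpha],
            "ci_mu_beta": [float(v) for v in self.ci_mu_beta],
            "level": float(self.level),
            "warnings": list(self.warnings),
            "r2_mean": float(self.individual["r2"].mean()),
        }


def _z_value(level: float, exact: bool) -> float:
    z = float(stats.norm.ppf(1 - (1 - level) / 2))
    return z if exact else round(z, 2)


def growth_confidence_interval(
    mean: float, se: float, level: float = 0.95, exact_z: bool = False
) -> tuple[float, float]:
    """Normal-theory interval mean +/- z * se.

    By convention the two-decimal multiplier (1.96 at the 95% level) is
    used; ``exact_z`` switches to the full-precision quantile (1.959964).
    """
    if se < 0:
        raise ValueError("standard error must be non-negative")
    z = _z_value(level, exact_z)
    return (mean - z * se, mean + z * se)


def aggregate_growth(
    individual: pd.DataFrame,
    coding: TimeCoding,
    level: float = 0.95,
    exact_z: bool = False,
    truncate_negative: bool = False,
) -> GrowthEstimates:
    """Aggregate per-individual fits into group growth parameters.

    ``individual`` needs columns alpha_hat, beta_hat, resid_var, r2. The
    variance components subtract the OLS sampling-noise share from the raw
    variance of the individual estimates; a negative corrected component
    is retained with a warning unless ``truncate_negative``.
    """
    if len(individual) < 2:
        raise ValueError("need at least 2 fitted individuals")
    alpha = individual["alpha_hat"].to_numpy()
    beta = individual["beta_hat"].to_numpy()
    n = len(individual)
    mu_a, mu_b = float(alpha.mean()), float(beta.mean())
    var_eps = float(individual["resid_var"].mean())
    var_a, var_b = float(alpha.var(ddof=1)), float(beta.var(ddof=1))

    noise_a = var_eps * coding.sum_sq / (coding.n_waves * coding.ss_lambda)
    noise_b = var_eps / coding.ss_lambda
    psi_aa = var_a - noise_a
    psi_bb = var_b - noise_b
    warnings = []
    for label, val in (("psi_aa", psi_aa), ("psi_bb", psi_bb)):
        if val < 0:
            warnings.append(
                f"{label} = {val:.4g} is negative after the sampling-noise "
                "correction; true between-person variance may be near zero"
            )
    if truncate_negative:
        psi_aa, psi_bb = max(psi_aa, 0.0), max(psi_bb, 0.0)

    se_a, se_b = np.sqrt(var_a / n), np.sqrt(var_b / n)
    out = individual.copy()
    out["zeta_alpha"] = alpha - mu_a
    out["zeta_beta"] = beta - mu_b
    return GrowthEstimates(
        individual=out,
        coding=coding,
        mu_alpha=mu_a,
        mu_beta=mu_b,
        var_eps=var_eps,
        psi_aa=float(psi_aa),
        psi_bb=float(psi_bb),
        var_alpha_hat=var_a,
        var_beta_hat=var_b,
        se_mu_alpha=float(se_a),
        se_mu_beta=float(se_b),
        ci_mu_alpha=growth_confidence_interval(mu_a, float(se_a), level, exact_z),
        ci_mu_beta=growth_confidence_interval(mu_b, float(se_b), level, exact_z),
        level=level,
        warnings=warnings,
    )


def implied_estimate_variance(
    coding: TimeCoding, psi: float, var_eps: float, which: str
) -> float:
    """Model-implied variance of the per-individual OLS estimates.

    The raw dispersion of the individual intercepts (slopes) equals the
    true between-person variance component plus the OLS sampling noise;
    this is the inverse of the correction applied in
    :func:`aggregate_growth`:

        var(alpha_hat) = psi_aa + var(eps) * sum(lambda^2) / (T * S_ll)
        var(beta_hat)  = psi_bb + var(eps) / S_ll
    """
    if which == "alpha":
        return psi + var_eps * coding.sum_sq / (coding.n_waves * coding.ss_lambda)
    if which == "beta":
        return psi + var_eps / coding.ss_lambda
    raise ValueError("which must be 'alpha' or 'beta'")


def mean_se_from_components(
    coding: TimeCoding, psi: float, var_eps: float, n: int, which: str
) -> float:
    """Standard error of the mean intercept/slope implied by the variance
    components: sqrt(implied estimate variance / N)."""
    return float(np.sqrt(implied_estimate_variance(coding, psi, var_eps, which) / n))


def growth_fit_summary(individual: pd.DataFrame, bins: int = 20) -> dict:
    """Distribution summaries of the individual fits: R^2 quantiles and
    histogram bin counts for the intercepts and slopes."""
    if len(individual) == 0:
        raise ValueError("no fitted individuals")
    r2 = individual["r2"].to_numpy()
    qs = [0, 0.25, 0.5, 0.75, 1.0]
    summary = {
        "r2": {
            "mean": float(r2.mean()),
            "quantiles": {str(q): float(np.quantile(r2, q)) for q in qs},
        }
    }
    for col in ("alpha_hat", "beta_hat"):
        vals = individual[col].to_numpy()
        counts, edges = np.histogram(vals, bins=bins)
        summary[col] = {
            "mean": float(vals.mean()),
            "min": float(vals.min()),
            "max": float(vals.max()),
            "hist_counts": counts.tolist(),
            "hist_edges": [float(e) for e in edges],
        }
    return summary
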