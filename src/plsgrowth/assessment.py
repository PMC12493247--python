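"""Measurement-model assessment: reliability, validity and collinearity.

Reflective blocks are judged on indicator loadings (>= 0.708, i.e. at least
half of an indicator's variance explained by its construct), internal
consistency (Cronbach's alpha as the lower bound, composite reliability
rho_c as the upper bound, Dijkstra-Henseler rho_A typically in between;
acceptable between 0.70 — 0.60 in exploratory work — and 0.95), convergent
validity (AVE >= 0.50) and discriminant validity via the heterotrait-
monotrait correlation ratio (HTMT < 0.90 for conceptually similar
constructs, < 0.85 otherwise).

Formative blocks are judged on convergent validity against a reflective or
single-item measure of the same concept (redundancy correlation >= 0.708),
indicator collinearity (VIF banded at 3 and 5), and the bootstrap
significance and relevance of indicator weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_spec import ModelSpec
from .pls import LatentScoreMatrix, OuterModel, standardize

__all__ = [
    "LOADING_THRESHOLD",
    "cronbach_alpha",
    "composite_reliability_rho_c",
    "rho_a",
    "ave",
    "indicator_loadings",
    "htmt",
    "htmt_matrix",
    "vif",
    "redundancy_analysis",
    "weight_significance",
    "evaluate_reflective",
    "evaluate_formative",
    "ReliabilityReport",
    "DiscriminantReport",
    "CollinearityReport",
]

LOADING_THRESHOLD = 0.708   # 0.708^2 ~ 0.50 communality
AVE_THRESHOLD = 0.50
RELIABILITY_FLOOR = 0.70
RELIABILITY_FLOOR_EXPLORATORY = 0.60
RELIABILITY_CEILING = 0.95
T_CUTOFFS = {0.10: 1.645, 0.05: 1.960, 0.01: 2.576}


@dataclass
class Flag:
    """A threshold check: the value, the threshold used and the verdict."""

    value: float | None
    threshold: str
    status: str  # 'pass' | 'warn' | 'fail' | 'absent'
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "value": None if self.value is None else float(self.value),
            "threshold": self.threshold,
            "status": self.status,
            "note": self.note,
        }


# ---------------------------------------------------------------------------
# reliability / convergent validity metrics
# ---------------------------------------------------------------------------

def cronbach_alpha(items) -> float:
    """Cronbach's alpha of an item block (covariance form).

    alpha = k/(k-1) * (1 - sum var(x_i) / var(sum x_i)); on standardized
    items this equals k*rbar / (1 + (k-1)*rbar) with rbar the mean
    inter-item correlation.
    """
    X = np.asarray(items, dtype=float)
    k = X.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    item_vars = X.var(axis=0, ddof=1)
    total_var = X.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("total score has zero variance")
    return float(k / (k - 1) * (1 - item_vars.sum() / total_var))


def composite_reliability_rho_c(loadings) -> float:
    """Composite reliability rho_c = (sum l)^2 / ((sum l)^2 + sum(1 - l^2))."""
    l = np.asarray(loadings, dtype=float)
    if l.size == 0:
        raise ValueError("empty loading set")
    s = l.sum() ** 2
    return float(s / (s + (1 - l**2).sum()))


def rho_a(weights, S) -> float | None:
    """Dijkstra-Henseler reliability rho_A from outer weights and the
    indicator correlation matrix:

        rho_A = (w'w)^2 * w'(S - diag S)w / w'(ww' - diag(ww'))w

    with w the PLS weights normalised to a unit-variance composite
    (w'Sw = 1). Returns None when the denominator degenerates (e.g. a
    single indicator).
    """
    w = np.asarray(weights, dtype=float)
    S = np.asarray(S, dtype=float)
    if w.size < 2:
        return None
    ww = np.outer(w, w)
    num = (w @ w) ** 2 * (w @ (S - np.diag(np.diag(S))) @ w)
    den = w @ (ww - np.diag(np.diag(ww))) @ w
    if den == 0:
        return None
    return float(num / den)


def ave(loadings) -> float:
    """Average variance extracted: mean squared indicator loading."""
    l = np.asarray(loadings, dtype=float)
    if l.size == 0:
        raise ValueError("empty loading set")
    return float(np.mean(l**2))


def indicator_loadings(
    scores: LatentScoreMatrix, std_items: pd.DataFrame, spec: ModelSpec
) -> dict[str, dict[str, Flag]]:
    """Correlation of each indicator with its own construct's score,
    flagged against the 0.708 floor."""
    n = len(std_items)
    out: dict[str, dict[str, Flag]] = {}
    for c in spec.constructs:
        y = scores.scores[c.name].to_numpy()
        flags = {}
        for item in c.items:
            x = std_items[item].to_numpy()
            if x.std(ddof=1) == 0:
                raise ValueError(f"zero-variance indicator {item!r}")
            load = float(x @ y / (n - 1) / (x.std(ddof=1) * y.std(ddof=1)))
            status = "pass" if load >= LOADING_THRESHOLD else "fail"
            flags[item] = Flag(load, f">= {LOADING_THRESHOLD}", status)
        out[c.name] = flags
    return out


# ---------------------------------------------------------------------------
# discriminant validity
# ---------------------------------------------------------------------------

def htmt(corr_a: np.ndarray, corr_b: np.ndarray, cross: np.ndarray) -> float | None:
    """HTMT for one construct pair from within- and cross-block
    correlation matrices (absolute correlations throughout).

    Returns None when a within-construct mean correlation is non-positive,
    leaving the ratio undefined.
    """
    ka, kb = corr_a.shape[0], corr_b.shape[0]
    iu_a, iu_b = np.triu_indices(ka, k=1), np.triu_indices(kb, k=1)
    # the guard uses signed correlations: items that disagree in sign have
    # no meaningful monotrait reliability to scale the ratio by
    if corr_a[iu_a].mean() <= 0 or corr_b[iu_b].mean() <= 0:
        return None
    within_a = np.abs(corr_a[iu_a]).mean()
    within_b = np.abs(corr_b[iu_b]).mean()
    hetero = np.abs(cross).mean()
    return float(hetero / np.sqrt(within_a * within_b))


@dataclass
class DiscriminantReport:
    """Pairwise HTMT matrix with the threshold verdicts."""

    htmt: pd.DataFrame
    threshold: float
    flags: dict[tuple[str, str], Flag]
    excluded: list[str] = field(default_factory=list)
    boot_upper: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        d = {
            "threshold": self.threshold,
            "matrix": {
                f"{a}|{b}": (None if np.isnan(v) else float(v))
                for (a, b), v in self.htmt.stack().items()
                if a < b
            },
            "flags": {f"{a}|{b}": f.to_dict() for (a, b), f in self.flags.items()},
            "excluded_single_item": list(self.excluded),
        }
        if self.boot_upper is not None:
            d["bootstrap_upper"] = {
                f"{a}|{b}": float(v)
                for (a, b), v in self.boot_upper.stack().items()
                if a < b
            }
        return d


def htmt_matrix(std_items: pd.DataFrame, spec: ModelSpec) -> DiscriminantReport:
    """HTMT for every pair of multi-item reflective constructs.

    Single-item constructs carry no monotrait correlations and are
    excluded with a note.
    """
    multi = [c for c in spec.constructs if c.mode == "reflective" and len(c.items) >= 2]
    excluded = [c.name for c in spec.constructs if c not in multi]
    names = [c.name for c in multi]
    R = np.corrcoef(std_items[[it for c in multi for it in c.items]].to_numpy(),
                    rowvar=False)
    # index ranges of each construct inside R
    pos, start = {}, 0
    for c in multi:
        pos[c.name] = slice(start, start + len(c.items))
        start += len(c.items)

    mat = pd.DataFrame(np.nan, index=names, columns=names)
    flags: dict[tuple[str, str], Flag] = {}
    thr = spec.options.htmt_threshold
    for i, a in enumerate(multi):
        for b in multi[i + 1:]:
            sa, sb = pos[a.name], pos[b.name]
            val = htmt(R[sa, sa], R[sb, sb], R[sa, sb])
            if val is None:
                flags[(a.name, b.name)] = Flag(
                    None, f"< {thr}", "absent",
                    "non-positive within-construct mean correlation",
                )
                continue
            mat.loc[a.name, b.name] = mat.loc[b.name, a.name] = val
            status = "pass" if val < thr else "fail"
            flags[(a.name, b.name)] = Flag(val, f"< {thr}", status)
    return DiscriminantReport(htmt=mat, threshold=thr, flags=flags, excluded=excluded)


# ---------------------------------------------------------------------------
# collinearity
# ---------------------------------------------------------------------------

@dataclass
class CollinearityReport:
    """VIF per column with the conventional 3 / 5 banding."""

    vif: dict[str, float]
    bands: dict[str, str]  # 'ok' | 'uncritical' | 'critical'
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "vif": {k: (float(v) if np.isfinite(v) else None) for k, v in self.vif.items()},
            "bands": dict(self.bands),
            "note": self.note,
        }


def _band(v: float) -> str:
    if v >= 5:
        return "critical"
    if v >= 3:
        return "uncritical"
    return "ok"


def vif(X: pd.DataFrame) -> CollinearityReport:
    """Variance inflation factors: VIF_j = 1 / (1 - R^2_j) from regressing
    column j on the remaining columns. Perfectly collinear columns report
    infinite VIF in the critical band."""
    cols = list(X.columns)
    if len(cols) < 2:
        return CollinearityReport(
            vif={c: 1.0 for c in cols}, bands={c: "ok" for c in cols},
            note="fewer than 2 columns; collinearity trivially absent",
        )
    Z = standardize(X).to_numpy()
    n = Z.shape[0]
    if n <= len(cols):
        raise ValueError("need more rows than columns for VIF")
    out, bands = {}, {}
    for j, c in enumerate(cols):
        others = np.delete(Z, j, axis=1)
        y = Z[:, j]
        beta, res, rank, _ = np.linalg.lstsq(others, y, rcond=None)
        sse = float(((y - others @ beta) ** 2).sum())
        sst = float((y**2).sum())
        r2 = 1 - sse / sst
        v = np.inf if r2 >= 1 - 1e-12 else 1.0 / (1.0 - r2)
        out[c] = float(v)
        bands[c] = _band(v)
    return CollinearityReport(vif=out, bands=bands)


# ---------------------------------------------------------------------------
# formative-specific checks
# ---------------------------------------------------------------------------

def redundancy_analysis(formative_score, global_score) -> Flag:
    """Convergent validity of a formative construct: correlation with a
    reflective or single-item measure of the same concept (>= 0.708)."""
    a = np.asarray(formative_score, dtype=float)
    b = np.asarray(global_score, dtype=float)
    r = float(np.corrcoef(a, b)[0, 1])
    return Flag(r, f">= {LOADING_THRESHOLD}", "pass" if r >= LOADING_THRESHOLD else "fail")


def weight_significance(
    estimates: dict[str, float],
    boot: pd.DataFrame,
    loadings: dict[str, float] | None = None,
    loading_boot: pd.DataFrame | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Bootstrap significance and relevance of formative indicator weights.

    t = estimate / bootstrap SE, judged against the two-tailed normal
    cutoffs 1.645 / 1.960 / 2.576; the percentile CI at ``level`` should
    exclude zero. An indicator with a non-significant weight is still
    flagged as relevant when its loading is >= 0.50 and itself
    significant.
    """
    lo_q, hi_q = (1 - level) / 2, 1 - (1 - level) / 2
    rows = []
    for item, est in estimates.items():
        reps = boot[item].to_numpy()
        se = float(reps.std(ddof=1)) if len(reps) > 1 else np.nan
        t = est / se if se and np.isfinite(se) and se > 0 else np.nan
        ci = (
            (float(np.quantile(reps, lo_q)), float(np.quantile(reps, hi_q)))
            if len(reps) > 1 else (np.nan, np.nan)
        )
        sig = _sig_level(t)
        relevant = sig is not None
        note = ""
        if not relevant and loadings is not None and item in loadings:
            load = loadings[item]
            l_t = np.nan
            if loading_boot is not None and item in loading_boot:
                l_se = float(loading_boot[item].to_numpy().std(ddof=1))
                l_t = load / l_se if l_se > 0 else np.nan
            if load >= 0.50 and np.isfinite(l_t) and abs(l_t) >= T_CUTOFFS[0.05]:
                relevant = True
                note = "retained: loading >= 0.50 and significant"
        rows.append(
            dict(item=item, estimate=est, boot_se=se, t=t,
                 ci_lo=ci[0], ci_hi=ci[1],
                 sig=sig if sig is not None else "ns",
                 relevant=bool(relevant), note=note)
        )
    return pd.DataFrame(rows).set_index("item")


def _sig_level(t: float) -> str | None:
    if not np.isfinite(t):
        return None
    a = abs(t)
    if a >= T_CUTOFFS[0.01]:
        return "p<0.01"
    if a >= T_CUTOFFS[0.05]:
        return "p<0.05"
    if a >= T_CUTOFFS[0.10]:
        return "p<0.10"
    return None


# ---------------------------------------------------------------------------
# construct-level reports and decision rules
# ---------------------------------------------------------------------------

@dataclass
class ReliabilityReport:
    """Per-construct reliability and convergent-validity values with flags."""

    values: pd.DataFrame  # columns: cronbach_alpha, rho_a, rho_c, ave
    flags: dict[str, dict[str, Flag]]
    loadings: dict[str, dict[str, Flag]]

    def to_dict(self) -> dict:
        return {
            "values": {
                c: {k: (None if pd.isna(v) else float(v)) for k, v in row.items()}
                for c, row in self.values.iterrows()
            },
            "flags": {
                c: {m: f.to_dict() for m, f in fl.items()} for c, fl in self.flags.items()
            },
            "loadings": {
                c: {i: f.to_dict() for i, f in fl.items()}
                for c, fl in self.loadings.items()
            },
        }


def _reliability_flag(value: float | None, exploratory: bool) -> Flag:
    floor = RELIABILITY_FLOOR_EXPLORATORY if exploratory else RELIABILITY_FLOOR
    thr = f"[{floor}, {RELIABILITY_CEILING}]"
    if value is None:
        return Flag(None, thr, "absent", "undefined for a single indicator")
    if value < floor:
        return Flag(value, thr, "fail")
    if value > RELIABILITY_CEILING:
        return Flag(value, thr, "warn", "above 0.95: possible indicator redundancy")
    note = "exploratory floor 0.60 applied" if exploratory and value < RELIABILITY_FLOOR else ""
    return Flag(value, thr, "pass", note)


def evaluate_reflective(
    outer: OuterModel,
    scores: LatentScoreMatrix,
    std_items: pd.DataFrame,
    spec: ModelSpec,
) -> tuple[ReliabilityReport, DiscriminantReport]:
    """Apply the reflective evaluation sequence: indicator loadings,
    internal consistency (alpha / rho_A / rho_c), AVE, then HTMT."""
    exploratory = spec.options.exploratory
    load_flags = indicator_loadings(scores, std_items, spec)
    n_items = {c.name: len(c.items) for c in spec.constructs}

    rows, flags = {}, {}
    for c in spec.constructs:
        fit = outer.constructs[c.name]
        lvec = fit.loadings
        if n_items[c.name] >= 2:
            block = std_items[list(c.items)].to_numpy()
            alpha = cronbach_alpha(block)
            S = np.corrcoef(block, rowvar=False)
            ra = rho_a(fit.weights, S)
            rc = composite_reliability_rho_c(lvec)
        else:
            alpha = ra = rc = None
        a_ve = ave(lvec)
        rows[c.name] = dict(
            cronbach_alpha=alpha, rho_a=ra, rho_c=rc, ave=a_ve
        )
        cf = {
            "cronbach_alpha": _reliability_flag(alpha, exploratory),
            "rho_a": _reliability_flag(ra, exploratory),
            "rho_c": _reliability_flag(rc, exploratory),
            "ave": Flag(
                a_ve, f">= {AVE_THRESHOLD}",
                "pass" if a_ve >= AVE_THRESHOLD else "fail",
            ),
        }
        flags[c.name] = cf
    values = pd.DataFrame.from_dict(rows, orient="index").astype(float)
    rel = ReliabilityReport(values=values, flags=flags, loadings=load_flags)
    disc = htmt_matrix(std_items, spec)
    return rel, disc


def evaluate_formative(
    outer: OuterModel,
    std_items: pd.DataFrame,
    spec: ModelSpec,
    redundancy: dict[str, Flag] | None = None,
    weight_tables: dict[str, pd.DataFrame] | None = None,
) -> dict[str, dict]:
    """Apply the formative evaluation sequence per formative construct:
    convergent validity (redundancy), indicator collinearity (VIF), and
    weight significance/relevance where a bootstrap table is supplied."""
    out: dict[str, dict] = {}
    for c in spec.constructs:
        if c.mode != "formative":
            continue
        entry: dict = {}
        if redundancy and c.name in redundancy:
            entry["redundancy"] = redundancy[c.name]
        if len(c.items) >= 2:
            entry["collinearity"] = vif(std_items[list(c.items)])
        else:
            entry["collinearity"] = CollinearityReport(
                vif={c.items[0]: 1.0}, bands={c.items[0]: "ok"},
                note="single indicator; collinearity trivially absent",
            )
        if weight_tables and c.name in weight_tables:
            entry["weights"] = weight_tables[c.name]
        out[c.name] = entry
    return out
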