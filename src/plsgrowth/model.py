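"""Model/Results interface tying the three stages together.

:class:`PLSGrowthModel` holds the data and the declarative specification;
``fit()`` executes Stage 1 (PLS estimation, measurement assessment, score
saving), Stage 2 (reverse standardization and growth estimation) and
Stage 3 (conditional structural model with bootstrap inference) and
returns a :class:`PLSGrowthResults` carrying every estimate, its
uncertainty and the threshold verdicts, with ``summary()`` and JSON/text
report writers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assessment import (
    DiscriminantReport,
    ReliabilityReport,
    evaluate_formative,
    evaluate_reflective,
    weight_significance,
)
from .growth import GrowthEstimates, TimeCoding, growth_fit_summary
from .model_spec import ModelSpec, parse_model_config
from .panel import PanelTable, impute_mean, load_panel_csv
from .pls import LatentScoreMatrix, OuterModel, standardize
from .structural import (
    BootstrapDistribution,
    StructuralResults,
    bootstrap_pipeline,
    run_stages,
    summarize_significance,
)

__all__ = ["PLSGrowthModel", "PLSGrowthResults", "run_pipeline", "write_report"]


class StageError(RuntimeError):
    """Pipeline failure annotated with the stage it occurred in."""

    def __init__(self, stage: str, original: Exception):
        super().__init__(f"[{stage}] {original}")
        self.stage = stage
        self.original = original


@dataclass
class PLSGrowthResults:
    """Fitted integrated model: estimates, uncertainty and diagnostics."""

    spec: ModelSpec
    outer: OuterModel
    scores: LatentScoreMatrix
    reliability: ReliabilityReport
    discriminant: DiscriminantReport
    formative: dict[str, dict]
    growth: GrowthEstimates
    structural: StructuralResults | None
    boot: BootstrapDistribution | None
    provenance: dict

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "provenance": dict(self.provenance),
            "measurement": {
                "reliability": self.reliability.to_dict(),
                "discriminant": self.discriminant.to_dict(),
                "formative": {
                    name: {
                        k: (v.to_dict() if hasattr(v, "to_dict") else _df_dict(v))
                        for k, v in entry.items()
                    }
                    for name, entry in self.formative.items()
                },
                "converged": self.outer.converged,
                "iterations": self.outer.iterations,
                "inner_paths": self.outer.inner_paths,
                "weights": {
                    c.name: {i: float(w) for i, w in zip(c.items, c.weights)}
                    for c in self.outer.constructs.values()
                },
            },
            "growth": self.growth.to_dict(),
            "growth_fit": growth_fit_summary(self.growth.individual),
            "structural": self.structural.to_dict() if self.structural else None,
            "bootstrap": self.boot.to_dict() if self.boot else None,
        }
        return d

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def save(self, path, format: str = "json") -> None:
        write_report(self, path, format=format)

    # -- exports -----------------------------------------------------------
    def individual_growth_frame(self) -> pd.DataFrame:
        """Per-respondent growth estimates (id, alpha_hat, beta_hat, ...)."""
        return self.growth.individual.copy()

    def path_table(self) -> pd.DataFrame:
        """Structural path table suitable for CSV export."""
        if self.structural is None:
            return pd.DataFrame()
        return self.structural.paths.reset_index()

    # -- display -----------------------------------------------------------
    def summary(self) -> str:
        lines = []
        p = self.provenance
        lines.append("Integrated PLS-SEM / Latent Growth Curve Model")
        lines.append("=" * 62)
        lines.append(
            f"N = {self.growth.n} respondents, T = {self.spec.n_waves} waves, "
            f"scheme = {self.spec.options.scheme}"
        )
        lines.append(
            f"PLS converged in {self.outer.iterations} iterations "
            f"(tol = {self.spec.options.tol:g})"
        )
        lines.append("")
        lines.append("Stage 1 - Measurement model")
        lines.append("-" * 62)
        lines.append("Reliability and convergent validity (thresholds: alpha/rho_A/")
        floor = 0.60 if self.spec.options.exploratory else 0.70
        lines.append(f"rho_c in [{floor:.2f}, 0.95]; AVE >= 0.50):")
        vals = self.reliability.values
        hdr = f"{'construct':<12}{'alpha':>8}{'rho_A':>8}{'rho_c':>8}{'AVE':>8}  flags"
        lines.append(hdr)
        for cname, row in vals.iterrows():
            flags = self.reliability.flags[cname]
            worst = _worst_status(f.status for f in flags.values())
            lines.append(
                f"{cname:<12}"
                + "".join(
                    f"{_fmt(row[k]):>8}"
                    for k in ("cronbach_alpha", "rho_a", "rho_c", "ave")
                )
                + f"  {worst}"
            )
        lines.append("")
        lines.append(
            f"Indicator loadings (threshold >= 0.708, i.e. communality >= 0.50):"
        )
        for cname, fl in self.reliability.loadings.items():
            frag = ", ".join(f"{i}={f.value:.3f}[{f.status}]" for i, f in fl.items())
            lines.append(f"  {cname}: {frag}")
        lines.append("")
        lines.append(
            f"Discriminant validity, HTMT (threshold < {self.discriminant.threshold}):"
        )
        mat = self.discriminant.htmt
        if len(mat):
            lines.append("  " + " ".join(f"{c:>8}" for c in [""] + list(mat.columns)))
            for rname, row in mat.iterrows():
                lines.append(
                    f"  {rname:>8} " + " ".join(_fmt(v).rjust(8) for v in row)
                )
        if self.discriminant.excluded:
            lines.append(
                f"  (single-item construct(s) excluded: "
                f"{', '.join(self.discriminant.excluded)})"
            )
        lines.append("")
        lines.append("Stage 2 - Growth model (linear trajectory, lambda_t = t - 1)")
        lines.append("-" * 62)
        g = self.growth
        lines.append(f"{'var(eps)':<12}{g.var_eps:>10.4f}")
        lines.append(f"{'mu_alpha':<12}{g.mu_alpha:>10.4f}  (SE {g.se_mu_alpha:.4f})")
        lines.append(f"{'mu_beta':<12}{g.mu_beta:>10.4f}  (SE {g.se_mu_beta:.4f})")
        lines.append(f"{'psi_aa':<12}{g.psi_aa:>10.4f}")
        lines.append(f"{'psi_bb':<12}{g.psi_bb:>10.4f}")
        lines.append(
            f"{'CI mu_alpha':<12}({g.ci_mu_alpha[0]:.4f}, {g.ci_mu_alpha[1]:.4f})"
        )
        lines.append(
            f"{'CI mu_beta':<12}({g.ci_mu_beta[0]:.4f}, {g.ci_mu_beta[1]:.4f})"
        )
        lines.append(f"mean individual R^2 = {g.individual['r2'].mean():.4f}")
        for w in g.warnings:
            lines.append(f"warning: {w}")
        lines.append("")
        if self.structural is not None:
            lines.append("Stage 3 - Conditional structural model")
            lines.append("-" * 62)
            s = self.structural
            cols = [c for c in ("estimate", "boot_se", "t", "ci_lo", "ci_hi", "sig")
                    if c in s.paths.columns]
            lines.append(
                f"{'path':<22}" + "".join(f"{c:>10}" for c in cols)
            )
            for (src, tgt), row in s.paths.iterrows():
                lines.append(
                    f"{src + ' -> ' + tgt:<22}"
                    + "".join(
                        (f"{row[c]:>10.4f}" if isinstance(row[c], (int, float, np.floating))
                         and np.isfinite(row[c]) else f"{str(row[c]):>10}")
                        for c in cols
                    )
                )
            for factor, eq in s.equations.items():
                r2 = eq.get("r2")
                lines.append(
                    f"{factor}: intercept = {eq['intercept']:.4f}, "
                    f"R^2 = {_fmt(r2)}"
                )
            if s.collinearity is not None:
                frag = ", ".join(
                    f"{k}={_fmt(v)}[{s.collinearity.bands[k]}]"
                    for k, v in s.collinearity.vif.items()
                )
                lines.append(f"predictor VIF (bands at 3 and 5): {frag}")
            if self.boot is not None:
                lines.append(
                    f"bootstrap: B = {self.boot.b_requested} "
                    f"({self.boot.n_failed} failed), seed = {self.boot.seed}, "
                    f"percentile CIs at {int(round(s.level * 100))}%"
                )
        else:
            lines.append("Stage 3 - skipped (no structural paths declared)")
        lines.append("")
        lines.append(
            f"plsgrowth {p.get('version', '')}, seed = {p.get('seed')}, "
            f"B = {p.get('bootstrap_b')}"
        )
        return "\n".join(lines)

    def plot_growth_distributions(self, bins: int = 20):
        """Histograms of the individual intercepts and slopes."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(9, 3.5))
        for ax, col, label in zip(
            axes, ("alpha_hat", "beta_hat"), ("intercept", "slope")
        ):
            ax.hist(self.growth.individual[col], bins=bins, edgecolor="white")
            ax.set_xlabel(f"individual {label}")
            ax.set_ylabel("count")
        fig.tight_layout()
        return fig


def _fmt(v) -> str:
    if v is None or (isinstance(v, float) and not np.isfinite(v)):
        return "--"
    return f"{v:.3f}"


def _worst_status(statuses) -> str:
    order = {"fail": 3, "warn": 2, "absent": 1, "pass": 0}
    worst = max(statuses, key=lambda s: order.get(s, 0))
    return worst


def _df_dict(v):
    if isinstance(v, pd.DataFrame):
        return json.loads(v.to_json(orient="index"))
    return v


class PLSGrowthModel:
    """Integrated PLS-SEM growth model for a wide-format panel table.

    Parameters
    ----------
    data : PanelTable or pandas.DataFrame
        One row per respondent; indicator columns for every construct.
    spec : ModelSpec
        Constructs, the ordered repeated series and structural paths.
    coding : TimeCoding, optional
        Time scores; defaults to the linear coding lambda_t = t - 1.
    """

    def __init__(self, data, spec: ModelSpec, coding: TimeCoding | None = None):
        if isinstance(data, pd.DataFrame):
            data = PanelTable(data)
        self.table: PanelTable = data
        self.spec = spec
        self.coding = coding or TimeCoding.linear(spec.n_waves)
        self.table.require_items(spec.all_items)

    @classmethod
    def from_csv(cls, data_path, config_path, na_tokens=None) -> "PLSGrowthModel":
        table = load_panel_csv(data_path, na_tokens=na_tokens)
        spec = parse_model_config(config_path)
        return cls(table, spec)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, spec: ModelSpec) -> "PLSGrowthModel":
        return cls(PanelTable(df), spec)

    def fit(
        self,
        bootstrap: bool | None = None,
        b: int | None = None,
        seed: int | None = None,
    ) -> PLSGrowthResults:
        """Run the three stages and return the fitted results.

        ``bootstrap`` defaults to running whenever structural paths are
        declared; ``b`` and ``seed`` override the spec options.
        """
        spec = self.spec
        b = spec.options.bootstrap_b if b is None else b
        seed = spec.options.seed if seed is None else seed
        if bootstrap is None:
            bootstrap = bool(spec.paths)

        try:
            table = impute_mean(self.table)
        except Exception as exc:
            raise StageError("Stage 1: imputation", exc) from exc

        try:
            outer, scores, growth, structural = run_stages(
                table, spec, coding=self.coding
            )
        except StageError:
            raise
        except Exception as exc:
            stage = "Stage 1: PLS estimation"
            if isinstance(exc, ValueError) and "composite" in str(exc):
                stage = "Stage 2: reverse standardization"
            raise StageError(stage, exc) from exc

        std_items = standardize(table.values[spec.all_items])
        try:
            reliability, discriminant = evaluate_reflective(
                outer, scores, std_items, spec
            )
        except Exception as exc:
            raise StageError("Stage 1: measurement assessment", exc) from exc

        boot = None
        if bootstrap:
            try:
                boot = bootstrap_pipeline(
                    table, spec, b=b, seed=seed, reference=outer, coding=self.coding
                )
                if structural is not None:
                    structural = summarize_significance(structural, boot)
            except Exception as exc:
                raise StageError("Stage 3: bootstrap", exc) from exc
            _attach_htmt_bounds(discriminant, boot, spec.options.level)

        weight_tables = None
        if boot is not None and boot.b_successful >= 2:
            weight_tables = {}
            for c in spec.constructs:
                if c.mode != "formative":
                    continue
                fit = outer.constructs[c.name]
                cols = {f"{c.name}:{i}": i for i in c.items}
                reps = boot.weights[list(cols)].rename(columns=cols)
                lreps = boot.loadings[list(cols)].rename(columns=cols)
                weight_tables[c.name] = weight_significance(
                    {i: float(w) for i, w in zip(fit.items, fit.weights)},
                    reps,
                    loadings={i: float(l) for i, l in zip(fit.items, fit.loadings)},
                    loading_boot=lreps,
                    level=spec.options.level,
                )
        formative = evaluate_formative(
            outer, std_items, spec, weight_tables=weight_tables
        )

        provenance = {
            "version": __version__,
            "seed": seed,
            "bootstrap_b": b if bootstrap else None,
            "tol": spec.options.tol,
            "max_iter": spec.options.max_iter,
            "scheme": spec.options.scheme,
            "level": spec.options.level,
            "n_respondents": table.n_respondents,
            "n_waves": spec.n_waves,
            "imputed_cells": int(table.missing_mask.to_numpy().sum()),
        }
        return PLSGrowthResults(
            spec=spec,
            outer=outer,
            scores=scores,
            reliability=reliability,
            discriminant=discriminant,
            formative=formative,
            growth=growth,
            structural=structural,
            boot=boot,
            provenance=provenance,
        )


def _attach_htmt_bounds(
    disc: DiscriminantReport, boot: BootstrapDistribution, level: float
) -> None:
    """Percentile-bootstrap upper bound of each HTMT value; a pair is only
    'significantly below' its threshold when this bound stays under it."""
    if boot.htmt.empty:
        return
    names = list(disc.htmt.columns)
    upper = pd.DataFrame(np.nan, index=names, columns=names)
    for col in boot.htmt.columns:
        a, b_name = col.split("|")
        if a in names and b_name in names:
            reps = boot.htmt[col].dropna().to_numpy()
            if len(reps) >= 2:
                u = float(np.quantile(reps, level))
                upper.loc[a, b_name] = upper.loc[b_name, a] = u
                flag = disc.flags.get((a, b_name))
                if flag is not None and flag.value is not None:
                    below = u < disc.threshold
                    note = (
                        f"bootstrap {int(round(level * 100))}% upper bound "
                        f"{u:.3f} {'<' if below else '>='} {disc.threshold}"
                    )
                    flag.note = (flag.note + "; " if flag.note else "") + note
    disc.boot_upper = upper


def run_pipeline(
    table: PanelTable, spec: ModelSpec, **fit_kwargs
) -> PLSGrowthResults:
    """Execute the full three-stage pipeline on a panel table.

    Thin functional wrapper over ``PLSGrowthModel(table, spec).fit(...)``.
    """
    return PLSGrowthModel(table, spec).fit(**fit_kwargs)


def write_report(results: PLSGrowthResults, path, format: str = "json") -> None:
    """Serialize a fitted model to disk.

    ``json`` writes every estimate, SE, CI and threshold flag at full
    precision; ``text`` writes the human-readable summary tables.
    """
    path = Path(path)
    if format == "json":
        path.write_text(results.to_json(indent=2) + "\n")
    elif format == "text":
        path.write_text(results.summary() + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
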