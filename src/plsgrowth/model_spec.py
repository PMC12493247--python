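"""Declarative model specification: constructs, the repeated series, paths.

The specification mirrors how PLS-SEM packages declare a model — a list of
constructs, each reflective, formative or single-item, plus structural
relationships — extended with the ordered *repeated series*: the T wave
instances of the outcome construct whose latent scores feed the growth
stage. Structural paths run from time-invariant predictor constructs to the
growth factors (intercept and/or slope).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path as _Path

import yaml

__all__ = [
    "Construct",
    "StructuralPath",
    "EngineOptions",
    "ModelSpec",
    "parse_model_config",
]

MODES = ("reflective", "formative", "single_item")
GROWTH_FACTORS = ("intercept", "slope")


class ModelSpecError(ValueError):
    """Raised for an invalid or inconsistent model specification."""


@dataclass(frozen=True)
class Construct:
    name: str
    mode: str
    items: tuple[str, ...]

    def __post_init__(self):
        if self.mode not in MODES:
            raise ModelSpecError(
                f"construct {self.name!r}: unknown mode {self.mode!r}; "
                f"expected one of {MODES}"
            )
        if not self.items:
            raise ModelSpecError(f"construct {self.name!r} declares no items")
        if self.mode == "single_item" and len(self.items) != 1:
            raise ModelSpecError(
                f"single_item construct {self.name!r} must have exactly one item"
            )
        if len(set(self.items)) != len(self.items):
            raise ModelSpecError(f"construct {self.name!r} repeats an item")


@dataclass(frozen=True)
class StructuralPath:
    """Directed path from a predictor construct to growth factors."""

    source: str
    targets: tuple[str, ...] = GROWTH_FACTORS

    def __post_init__(self):
        bad = [t for t in self.targets if t not in GROWTH_FACTORS]
        if bad:
            raise ModelSpecError(
                f"path from {self.source!r}: unknown growth factor(s) {bad}; "
                f"targets must be among {GROWTH_FACTORS}"
            )


@dataclass(frozen=True)
class EngineOptions:
    """Estimation options shared across the three stages.

    scheme : inner weighting scheme for the PLS algorithm
        ('path', 'centroid' or 'factorial').
    tol, max_iter : PLS convergence control (max |Δ outer weight|).
    bootstrap_b : number of bootstrap resamples for Stage-3 inference.
    seed : base seed for all randomness (bootstrap resampling).
    level : confidence level for all reported intervals.
    exploratory : relax the reliability floor from 0.70 to 0.60.
    htmt_threshold : discriminant-validity cutoff (0.90 for conceptually
        similar constructs, 0.85 for conceptually different ones).
    z_exact : use the full-precision normal quantile for growth CIs
        instead of the conventional two-decimal 1.96.
    """

    scheme: str = "path"
    tol: float = 1e-7
    max_iter: int = 300
    bootstrap_b: int = 2000
    seed: int = 123
    level: float = 0.95
    exploratory: bool = False
    htmt_threshold: float = 0.90
    z_exact: bool = False

    def __post_init__(self):
        if self.scheme not in ("path", "centroid", "factorial"):
            raise ModelSpecError(f"unknown inner weighting scheme {self.scheme!r}")
        if not 0 < self.level < 1:
            raise ModelSpecError("confidence level must lie in (0, 1)")
        if self.htmt_threshold not in (0.85, 0.90):
            raise ModelSpecError("htmt_threshold must be 0.85 or 0.90")


@dataclass(frozen=True)
class ModelSpec:
    """Measurement + structural design for the integrated model.

    Parameters
    ----------
    constructs : declared lower-order constructs (wave instances of the
        repeated outcome plus time-invariant predictors).
    repeated_series : ordered names of the T wave constructs (wave order).
        Needs T >= 3: the per-individual residual variance divides by T-2.
    growth_name : label for the higher-order growth block.
    paths : structural paths from predictors to growth factors.
    options : estimation options.
    """

    constructs: tuple[Construct, ...]
    repeated_series: tuple[str, ...]
    growth_name: str = "GROWTH"
    paths: tuple[StructuralPath, ...] = ()
    options: EngineOptions = field(default_factory=EngineOptions)

    def __post_init__(self):
        names = [c.name for c in self.constructs]
        if len(set(names)) != len(names):
            raise ModelSpecError("duplicate construct names")
        all_items = [it for c in self.constructs for it in c.items]
        if len(set(all_items)) != len(all_items):
            shared = sorted({it for it in all_items if all_items.count(it) > 1})
            raise ModelSpecError(f"item(s) assigned to more than one construct: {shared}")
        if len(self.repeated_series) < 3:
            raise ModelSpecError(
                f"repeated series has T={len(self.repeated_series)} waves; "
                "at least 3 are required (the per-individual residual "
                "variance has T-2 degrees of freedom)"
            )
        known = set(names)
        missing = [r for r in self.repeated_series if r not in known]
        if missing:
            raise ModelSpecError(f"repeated series names undeclared construct(s): {missing}")
        rep = set(self.repeated_series)
        for p in self.paths:
            if p.source not in known:
                raise ModelSpecError(f"path source {p.source!r} is not a declared construct")
            if p.source in rep:
                raise ModelSpecError(
                    f"path source {p.source!r} belongs to the repeated series; "
                    "predictors must be time-invariant"
                )

    # -- convenience views -------------------------------------------------
    @property
    def construct_names(self) -> list[str]:
        return [c.name for c in self.constructs]

    @property
    def predictor_names(self) -> list[str]:
        """Predictor constructs, in declaration order, that appear in a path."""
        sources = {p.source for p in self.paths}
        return [c.name for c in self.constructs if c.name in sources]

    @property
    def n_waves(self) -> int:
        return len(self.repeated_series)

    def construct(self, name: str) -> Construct:
        for c in self.constructs:
            if c.name == name:
                return c
        raise KeyError(name)

    def items_of(self, name: str) -> list[str]:
        return list(self.construct(name).items)

    @property
    def all_items(self) -> list[str]:
        return [it for c in self.constructs for it in c.items]

    def with_options(self, **kwargs) -> "ModelSpec":
        return replace(self, options=replace(self.options, **kwargs))


def _as_construct(entry: dict) -> Construct:
    try:
        name = entry["name"]
        mode = entry.get("mode", "reflective")
        items = entry["items"]
    except (KeyError, TypeError) as exc:
        raise ModelSpecError(f"malformed construct entry {entry!r}") from exc
    if isinstance(items, str):
        items = [items]
    return Construct(name=str(name), mode=str(mode), items=tuple(map(str, items)))


def parse_model_config(path) -> ModelSpec:
    """Parse a YAML (or JSON) model configuration file.

    Expected layout::

        constructs:
          - {name: SAT1, mode: reflective, items: [SA11, SA13, SA14]}
          - {name: Income, mode: single_item, items: [STINC11]}
        repeated_series: [SAT1, SAT2, SAT3]
        growth_name: GROWTH
        paths:
          - {from: PSYCO, to: [intercept, slope]}
          - {from: Income, to: GROWTH}        # growth_name == both factors
        options: {scheme: path, bootstrap_b: 2000, seed: 123}

    Unspecified options take the defaults of :class:`EngineOptions`
    (path weighting, tol 1e-7, 300 iterations, B=2000, seed 123, 95% level).
    """
    text = _Path(path).read_text()
    cfg = yaml.safe_load(text) if not str(path).endswith(".json") else json.loads(text)
    if not isinstance(cfg, dict):
        raise ModelSpecError(f"config {path} did not parse to a mapping")
    constructs = tuple(_as_construct(e) for e in cfg.get("constructs", []))
    series = tuple(map(str, cfg.get("repeated_series", [])))
    growth_name = str(cfg.get("growth_name", "GROWTH"))

    paths = []
    for entry in cfg.get("paths", []) or []:
        src = entry.get("from") or entry.get("source")
        to = entry.get("to", entry.get("targets", growth_name))
        if src is None:
            raise ModelSpecError(f"path entry missing 'from': {entry!r}")
        if isinstance(to, str):
            to = GROWTH_FACTORS if to == growth_name else (to,)
        paths.append(StructuralPath(source=str(src), targets=tuple(to)))

    opt_cfg = dict(cfg.get("options", {}) or {})
    known = set(EngineOptions.__dataclass_fields__)
    unknown = set(opt_cfg) - known
    if unknown:
        raise ModelSpecError(f"unknown option key(s): {sorted(unknown)}")
    if "tol" in opt_cfg:
        opt_cfg["tol"] = float(opt_cfg["tol"])
    options = EngineOptions(**opt_cfg)

    return ModelSpec(
        constructs=constructs,
        repeated_series=series,
        growth_name=growth_name,
        paths=tuple(paths),
        options=options,
    )
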