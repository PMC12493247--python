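"""Shared fixtures: synthetic panels and model designs."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plsgrowth import (
    Construct,
    EngineOptions,
    ModelSpec,
    PanelTable,
    StructuralPath,
)
from plsgrowth.simulate import SimulationParams, model_spec_for, simulate_panel


def exact_corr_data(R: np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    """Data whose *sample* correlation matrix equals R exactly.

    Random columns are orthonormalised (after centring) and then mixed by
    the Cholesky factor of R, so closed-form metric values can be asserted
    without sampling error.
    """
    R = np.asarray(R, dtype=float)
    k = R.shape[0]
    X = rng.normal(size=(n, k))
    X -= X.mean(axis=0)
    Q, _ = np.linalg.qr(X)
    Q -= Q.mean(axis=0)
    # re-orthonormalise after the second centring
    Q, _ = np.linalg.qr(Q)
    L = np.linalg.cholesky(R)
    Z = Q @ L.T
    return (Z - Z.mean(axis=0)) / Z.std(axis=0, ddof=1)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)


@pytest.fixture(scope="session")
def survey_spec() -> ModelSpec:
    """Three-wave life-satisfaction design: three reflective wave
    constructs, two reflective predictors, one single-item predictor,
    all predictors pointing at both growth factors."""
    return ModelSpec(
        constructs=(
            Construct("SAT1", "reflective", ("SA11", "SA13", "SA14")),
            Construct("SAT2", "reflective", ("SA21", "SA23", "SA24")),
            Construct("SAT3", "reflective", ("SA31", "SA33", "SA34")),
            Construct("PSYCO", "reflective", ("SPWB32", "SPWB33", "SPWB36")),
            Construct("SOC", "reflective", ("SSWB32", "SSWB34")),
            Construct("Income", "single_item", ("STINC11",)),
        ),
        repeated_series=("SAT1", "SAT2", "SAT3"),
        paths=(
            StructuralPath("PSYCO"),
            StructuralPath("SOC"),
            StructuralPath("Income"),
        ),
        options=EngineOptions(bootstrap_b=100, seed=123),
    )


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic panel with its truth and matching spec."""
    params = SimulationParams(seed=11)
    table, truth = simulate_panel(params)
    return params, table, truth, model_spec_for(params)


@pytest.fixture()
def tiny_table() -> PanelTable:
    rng = np.random.default_rng(3)
    df = pd.DataFrame(rng.normal(size=(12, 4)), columns=list("abcd"))
    return PanelTable(df)
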