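"""Iterative PLS-SEM weight estimation and latent-score extraction.

Implements the classical composite-based algorithm: latent scores start as
unit-weight composites of their standardized indicators, then alternate
between an inner approximation (combining neighbouring constructs' scores
under a chosen weighting scheme) and an outer update (correlation weights
for reflective blocks — Mode A — or regression weights for formative
blocks — Mode B) until the outer weights stabilise.

For the integrated growth model, the Stage-1 construct graph links every
time-invariant predictor construct to every wave instance of the repeated
outcome construct; the wave constructs are not linked to each other. The
converged, standardized scores of all lower-order constructs are then
"saved" — the disjoint two-stage step — and carried into the growth and
structural stages in place of the raw items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_spec import ModelSpec
from .panel import PanelTable

__all__ = [
    "standardize",
    "estimate_pls",
    "disjoint_stage_scores",
    "OuterModel",
    "ConstructFit",
    "LatentScoreMatrix",
    "PLSConvergenceError",
]


class PLSConvergenceError(RuntimeError):
    """PLS weight iteration failed to converge within max_iter."""

    def __init__(self, msg: str, last_delta: float):
        super().__init__(msg)
        self.last_delta = last_delta


def standardize(matrix, ddof: int = 1):
    """Z-score every column: mean 0, standard deviation 1 (N-1 denominator).

    Accepts a DataFrame or 2-d array; returns the same type. Raises on a
    constant column, naming the offending item where names are available.
    """
    is_df = isinstance(matrix, pd.DataFrame)
    X = matrix.to_numpy(dtype=float) if is_df else np.asarray(matrix, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        names = (
            [matrix.columns[i] for i in zero] if is_df else [f"column {i}" for i in zero]
        )
        raise ValueError(f"constant (zero-variance) item(s): {names}")
    Z = (X - mu) / sd
    if is_df:
        return pd.DataFrame(Z, index=matrix.index, columns=matrix.columns)
    return Z


@dataclass
class ConstructFit:
    """Converged outer solution for one construct."""

    name: str
    mode: str
    items: tuple[str, ...]
    weights: np.ndarray   # normalised so the composite has unit variance
    loadings: np.ndarray  # correlation of each indicator with the score


@dataclass
class OuterModel:
    """Converged measurement model: one :class:`ConstructFit` per construct,
    plus the Stage-1 inner path coefficients (each wave construct regressed
    on the predictor scores) for diagnostic use."""

    constructs: dict[str, ConstructFit]
    converged: bool
    iterations: int
    last_delta: float
    inner_paths: dict[str, dict[str, float]]

    def weights_vector(self) -> np.ndarray:
        return np.concatenate([c.weights for c in self.constructs.values()])


@dataclass
class LatentScoreMatrix:
    """Respondent x construct matrix of standardized latent scores."""

    scores: pd.DataFrame

    @property
    def construct_names(self) -> list[str]:
        return list(self.scores.columns)

    def check_standardized(self, atol: float = 1e-8) -> None:
        arr = self.scores.to_numpy()
        if np.abs(arr.mean(axis=0)).max() > atol:
            raise AssertionError("latent scores not centred")
        if np.abs(arr.std(axis=0, ddof=1) - 1).max() > atol:
            raise AssertionError("latent scores not unit-variance")

    def subset(self, names: list[str]) -> "LatentScoreMatrix":
        return LatentScoreMatrix(self.scores[names].copy())


def _stage1_graph(spec: ModelSpec) -> tuple[dict[int, list[int]], dict[int, list[int]]]:
    """Predecessor/successor index maps for the Stage-1 estimation graph."""
    idx = {name: j for j, name in enumerate(spec.construct_names)}
    preds: dict[int, list[int]] = {j: [] for j in idx.values()}
    succs: dict[int, list[int]] = {j: [] for j in idx.values()}
    sources = [idx[s] for s in spec.predictor_names]
    for wave in spec.repeated_series:
        w = idx[wave]
        for s in sources:
            preds[w].append(s)
            succs[s].append(w)
    return preds, succs


def _pls_core(
    X: np.ndarray,
    blocks: list[slice],
    modes: list[str],
    preds: dict[int, list[int]],
    succs: dict[int, list[int]],
    scheme: str,
    tol: float,
    max_iter: int,
    names: list[str],
) -> tuple[list[np.ndarray], np.ndarray, int, float]:
    """Numpy-only PLS weight iteration on a standardized item matrix.

    Returns (weights per block, score matrix, iterations, last delta);
    raises :class:`PLSConvergenceError` when max_iter is exhausted. This
    is the hot path shared by the public API and the bootstrap.
    """
    n = X.shape[0]
    J = len(blocks)

    # unit-weight initialisation, rescaled to unit composite variance
    W = []
    for b in blocks:
        w = np.ones(b.stop - b.start)
        y = X[:, b] @ w
        W.append(w / y.std(ddof=1))

    converged = False
    it = 0
    delta = np.inf
    Y = np.empty((n, J))
    for it in range(1, max_iter + 1):
        for j, b in enumerate(blocks):
            Y[:, j] = X[:, b] @ W[j]
        C = (Y.T @ Y) / (n - 1)

        # inner proxies
        Z = np.empty_like(Y)
        for j in range(J):
            nb = preds[j] + succs[j]
            if not nb:
                Z[:, j] = Y[:, j]
                continue
            e = np.zeros(J)
            if scheme == "centroid":
                e[nb] = np.sign(C[j, nb])
            elif scheme == "factorial":
                e[nb] = C[j, nb]
            else:  # path weighting
                if preds[j]:
                    p = preds[j]
                    e[p] = np.linalg.solve(C[np.ix_(p, p)], C[p, j])
                if succs[j]:
                    e[succs[j]] = C[j, succs[j]]
            z = Y @ e
            sd = z.std(ddof=1)
            Z[:, j] = Y[:, j] if sd == 0 else z / sd

        # outer update
        delta = 0.0
        for j, b in enumerate(blocks):
            Xb = X[:, b]
            cov = Xb.T @ Z[:, j] / (n - 1)
            if modes[j] == "formative":
                S = Xb.T @ Xb / (n - 1)
                try:
                    w = np.linalg.solve(S, cov)
                except np.linalg.LinAlgError as exc:
                    raise ValueError(
                        f"singular indicator block for formative construct "
                        f"{names[j]!r}"
                    ) from exc
            else:
                w = cov.copy()
            y = Xb @ w
            sd = y.std(ddof=1)
            if sd == 0:
                raise ValueError(f"degenerate composite for construct {names[j]!r}")
            w /= sd
            # sign convention: sum of indicator loadings positive
            if (Xb.T @ y).sum() < 0:
                w = -w
            delta = max(delta, np.abs(w - W[j]).max())
            W[j] = w
        if delta < tol:
            converged = True
            break

    if not converged:
        raise PLSConvergenceError(
            f"PLS did not converge in {max_iter} iterations "
            f"(last max |dw| = {delta:.3e})",
            last_delta=float(delta),
        )

    for j, b in enumerate(blocks):
        Y[:, j] = X[:, b] @ W[j]
    return W, Y, it, float(delta)


def _spec_layout(spec: ModelSpec):
    """Block slices, modes and the Stage-1 graph for a specification."""
    blocks: list[slice] = []
    start = 0
    for c in spec.constructs:
        blocks.append(slice(start, start + len(c.items)))
        start += len(c.items)
    modes = [c.mode for c in spec.constructs]
    preds, succs = _stage1_graph(spec)
    return blocks, modes, preds, succs


def estimate_pls(
    table: PanelTable, spec: ModelSpec
) -> tuple[OuterModel, LatentScoreMatrix]:
    """Run the PLS algorithm and return the outer model with latent scores.

    The panel must be complete (impute first); every item referenced by the
    spec must be present. Convergence is declared when the largest absolute
    change in any outer weight falls below ``spec.options.tol``.
    """
    if table.has_missing:
        raise ValueError("panel table has unimputed missing cells")
    items = spec.all_items
    table.require_items(items)
    X = standardize(table.values[items]).to_numpy()
    n = X.shape[0]
    blocks, modes, preds, succs = _spec_layout(spec)
    names = spec.construct_names
    W, Y, it, delta = _pls_core(
        X, blocks, modes, preds, succs,
        spec.options.scheme, spec.options.tol, spec.options.max_iter, names,
    )

    fits: dict[str, ConstructFit] = {}
    for j, (c, b) in enumerate(zip(spec.constructs, blocks)):
        loadings = X[:, b].T @ Y[:, j] / (n - 1)
        fits[c.name] = ConstructFit(
            name=c.name, mode=c.mode, items=c.items, weights=W[j], loadings=loadings
        )

    C = (Y.T @ Y) / (n - 1)
    inner: dict[str, dict[str, float]] = {}
    for j in range(len(blocks)):
        if preds[j]:
            p = preds[j]
            coef = np.linalg.solve(C[np.ix_(p, p)], C[p, j])
            inner[names[j]] = {names[k]: float(v) for k, v in zip(p, coef)}

    scores = LatentScoreMatrix(
        pd.DataFrame(Y, index=table.values.index, columns=names)
    )
    outer = OuterModel(
        constructs=fits,
        converged=True,
        iterations=it,
        last_delta=float(delta),
        inner_paths=inner,
    )
    return outer, scores


def disjoint_stage_scores(
    table: PanelTable, spec: ModelSpec, constructs: list[str] | None = None
) -> LatentScoreMatrix:
    """First stage of the disjoint two-stage approach: estimate all
    lower-order constructs and save their latent scores.

    The saved scores — not the raw items — feed the growth and structural
    stages. ``constructs`` optionally restricts the returned columns (e.g.
    predictors only); estimation always uses the full specification.
    """
    _, scores = estimate_pls(table, spec)
    if constructs is not None:
        return scores.subset(constructs)
    return scores
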