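"""Elastic-net regression with both penalties chosen by embedded CV.

The objective is taken literally as

    beta = argmin ||y - X beta||^2 + lam2 ||beta||^2 + lam1 ||beta||_1

with no 1/(2n) factor, solved by cyclic coordinate descent on standardized
columns and centered y.  The coordinate update is

    beta_j <- S(x_j' r_j, lam1 / 2) / (x_j' x_j + lam2)

where ``r_j`` is the partial residual excluding column j and S is the
soft-threshold operator; beta is identically zero once
lam1 >= 2 max|X' y|.  The mapping to the common per-observation
parameterization (used only when cross-checking against other solvers) is
``alpha * l1_ratio = lam1 / (2n)`` and ``alpha * (1 - l1_ratio) = lam2 / n``.

Both penalties are selected simultaneously on a (mixing ratio x lambda
ladder) grid by k-fold cross-validation of the training set, stratified by
outcome, with warm starts down each ladder.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

try:  # the inner loop is scalar-heavy; JIT it when numba is present
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def deco(f):
            return f
        return deco(args[0]) if args and callable(args[0]) else deco


class ConvergenceError(RuntimeError):
    """Coordinate descent hit the sweep limit; carries the last iterate."""

    def __init__(self, message, beta):
        super().__init__(message)
        self.beta = beta


@dataclass
class DesignMatrix:
    """Feature matrix / outcome pair plus column bookkeeping.

    Zero-variance columns cannot be standardized; they are dropped before
    fitting (recorded in ``dropped_columns``) and restored with beta = 0 in
    the fitted model so output ordering never changes.
    """

    X: np.ndarray
    y: np.ndarray
    column_labels: list

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.size:
            raise ValueError("X must be n x p with matching y")
        if self.X.shape[0] == 0 or self.X.shape[1] == 0:
            raise ValueError("empty design")
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("design contains missing values")
        if self.column_labels is None:
            self.column_labels = [f"x{j}" for j in range(self.X.shape[1])]
        if len(self.column_labels) != self.X.shape[1]:
            raise ValueError("column_labels length mismatch")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ElasticNetModel:
    """Fitted model on the original feature scale.

    ``beta`` includes zeros for any dropped (zero-variance) columns, so
    ``predict`` applies directly to unstandardized features in training
    column order.
    """

    intercept: float
    beta: np.ndarray
    lam1: float
    lam2: float
    column_labels: list
    feature_means: np.ndarray
    feature_sds: np.ndarray
    dropped_columns: list = field(default_factory=list)
    n_sweeps: int = 0

    @property
    def k(self) -> int:
        return count_selected(self)

    def to_json_dict(self) -> dict:
        return {
            "intercept": float(self.intercept),
            "coefficients": {
                lbl: float(b) for lbl, b in zip(self.column_labels, self.beta)
            },
            "lam1": float(self.lam1),
            "lam2": float(self.lam2),
            "feature_means": [float(v) for v in self.feature_means],
            "feature_sds": [float(v) for v in self.feature_sds],
            "dropped_columns": list(self.dropped_columns),
            "k": int(self.k),
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "ElasticNetModel":
        labels = list(d["coefficients"])
        return cls(
            intercept=d["intercept"],
            beta=np.array([d["coefficients"][l] for l in labels]),
            lam1=d["lam1"],
            lam2=d["lam2"],
            column_labels=labels,
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_sds=np.asarray(d["feature_sds"], dtype=float),
            dropped_columns=list(d.get("dropped_columns", [])),
        )


def count_selected(model: ElasticNetModel) -> int:
    """Number of strictly nonzero coefficients (the k of the df pair)."""
    return int(np.count_nonzero(model.beta))


def predict(model: ElasticNetModel, X_new) -> np.ndarray:
    """Linear scores ``intercept + X beta`` on the original feature scale."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.beta.size:
        raise ValueError(
            f"expected {model.beta.size} columns, got {X_new.shape[1]}"
        )
    return model.intercept + X_new @ model.beta


@njit(cache=True)
def _cd_kernel(G, c, lam1, lam2, beta, tol, max_sweeps):  # pragma: no cover
    p = G.shape[0]
    half = lam1 / 2.0
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            rho = c[j] - np.dot(G[j], beta) + G[j, j] * beta[j]
            if rho > half:
                bj = (rho - half) / (G[j, j] + lam2)
            elif rho < -half:
                bj = (rho + half) / (G[j, j] + lam2)
            else:
                bj = 0.0
            d = abs(bj - beta[j])
            if d > max_delta:
                max_delta = d
            beta[j] = bj
        if max_delta < tol:
            return sweep + 1
    return -1


def _objective(Xs, yc, beta, lam1, lam2) -> float:
    r = yc - Xs @ beta
    return float(r @ r + lam2 * beta @ beta + lam1 * np.abs(beta).sum())


def _cd_python(Xs, yc, G, c, lam1, lam2, beta, tol, max_sweeps):
    """Reference coordinate descent asserting objective monotonicity."""
    p = G.shape[0]
    obj = _objective(Xs, yc, beta, lam1, lam2)
    for sweep in range(max_sweeps):
        max_delta = 0.0
        for j in range(p):
            rho = c[j] - G[j] @ beta + G[j, j] * beta[j]
            bj = np.sign(rho) * max(abs(rho) - lam1 / 2.0, 0.0) / (G[j, j] + lam2)
            max_delta = max(max_delta, abs(bj - beta[j]))
            beta[j] = bj
        new_obj = _objective(Xs, yc, beta, lam1, lam2)
        assert new_obj <= obj + 1e-9 * max(1.0, abs(obj)), "objective increased"
        obj = new_obj
        if max_delta < tol:
            return sweep + 1
    return -1


def _standardize(design: DesignMatrix):
    means = design.X.mean(axis=0)
    sds = design.X.std(axis=0)
    keep = sds > 0
    Xs = (design.X[:, keep] - means[keep]) / sds[keep]
    y_mean = design.y.mean()
    return Xs, design.y - y_mean, y_mean, means, sds, keep


def fit_elastic_net(
    design: DesignMatrix,
    lam1: float,
    lam2: float,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    beta0: Optional[np.ndarray] = None,
    debug: bool = False,
) -> ElasticNetModel:
    """Solve the penalized objective for one (lam1, lam2) pair.

    ``beta0`` warm-starts the standardized coefficients.  ``debug=True``
    runs a pure-Python sweep that asserts the objective never increases.
    Raises :class:`ConvergenceError` (carrying the last iterate) if the
    sweep limit is reached.
    """
    if lam1 < 0 or lam2 < 0:
        raise ValueError("penalties must be nonnegative")
    Xs, yc, y_mean, means, sds, keep = _standardize(design)
    G = Xs.T @ Xs
    c = Xs.T @ yc
    beta = (
        np.zeros(Xs.shape[1]) if beta0 is None else np.asarray(beta0, dtype=float).copy()
    )
    if debug:
        sweeps = _cd_python(Xs, yc, G, c, lam1, lam2, beta, tol, max_sweeps)
    else:
        sweeps = _cd_kernel(G, c, float(lam1), float(lam2), beta, tol, max_sweeps)
    if sweeps < 0:
        raise ConvergenceError(
            f"coordinate descent did not converge in {max_sweeps} sweeps", beta
        )
    # back to the original scale, zeros restored for dropped columns
    beta_full = np.zeros(design.p)
    beta_full[keep] = beta / sds[keep]
    intercept = y_mean - beta_full @ means
    return ElasticNetModel(
        intercept=float(intercept),
        beta=beta_full,
        lam1=float(lam1),
        lam2=float(lam2),
        column_labels=list(design.column_labels),
        feature_means=means,
        feature_sds=sds,
        dropped_columns=[
            design.column_labels[j] for j in np.flatnonzero(~keep)
        ],
        n_sweeps=sweeps,
    )


def lam1_kill_threshold(design: DesignMatrix) -> float:
    """Smallest lam1 at which the solution is exactly zero: 2 max|X' y|
    (standardized X, centered y)."""
    Xs, yc, *_ = _standardize(design)
    return 2.0 * float(np.abs(Xs.T @ yc).max())


@dataclass
class CVResult:
    """Grid search record: candidate penalties, mean held-out squared error
    per cell, the chosen pair and the fold assignment used."""

    grid: pd.DataFrame  # columns: mixing_ratio, lam1, lam2, mean_cv_mse
    lam1: float
    lam2: float
    fold_assignments: np.ndarray
    seed: int

    def to_tsv(self, path) -> None:
        self.grid.to_csv(path, sep="\t", index=False)


def _stratified_folds(y: np.ndarray, n_folds: int, rng) -> np.ndarray:
    """Outcome-stratified folds: rows sorted by y are dealt into folds in
    shuffled blocks, so each fold spans the outcome range."""
    n = y.size
    order = np.argsort(y, kind="stable")
    folds = np.empty(n, dtype=np.int64)
    for start in range(0, n, n_folds):
        block = order[start : start + n_folds]
        ids = rng.permutation(n_folds)[: block.size]
        folds[block] = ids
    return folds


def default_penalty_grid(
    design: DesignMatrix,
    n_ratios: int = 10,
    n_lambdas: int = 50,
    decades: float = 4.0,
):
    """(mixing ratio, lam1, lam2) candidates: 10 ratios x a 50-point lam1
    ladder log-spaced from the kill threshold down ``decades`` decades, with
    lam2 = lam1 (1 - m) / m for mixing ratio m (m = 1 is the pure-L1 edge)."""
    lam1_max = lam1_kill_threshold(design)
    if lam1_max == 0:
        lam1_max = 1.0
    ratios = np.linspace(0.1, 1.0, n_ratios)
    ladder = lam1_max * np.logspace(0, -decades, n_lambdas)
    cells = []
    for m in ratios:
        for lam1 in ladder:
            cells.append((m, lam1, lam1 * (1.0 - m) / m))
    return cells


def cross_validate_penalties(
    design: DesignMatrix,
    n_folds: int = 10,
    grid=None,
    seed: int = 0,
    tol: float = 1e-7,
    max_sweeps: int = 10_000,
    max_fold_retries: int = 10,
) -> CVResult:
    """Choose (lam1, lam2) by k-fold CV of the training set.

    Folds are stratified by outcome; a fold whose held-in outcome has zero
    variance triggers a bounded re-draw.  Ties within 1e-12 of the minimum
    mean CV error resolve to the largest lam1, then the largest lam2
    (sparsest, then smoothest, candidate).
    """
    if not 2 <= n_folds <= design.n:
        raise ValueError("need n >= n_folds >= 2")
    rng = np.random.default_rng(seed)
    folds = None
    for _ in range(max_fold_retries):
        cand = _stratified_folds(design.y, n_folds, rng)
        ok = all(
            np.ptp(design.y[cand != f]) > 0 for f in range(n_folds)
        )
        if ok:
            folds = cand
            break
    if folds is None:
        raise ValueError("could not build folds with non-constant outcomes")

    if grid is None:
        grid = default_penalty_grid(design)
    cells = list(grid)

    sse = np.zeros(len(cells))
    for f in range(n_folds):
        tr = folds != f
        te = ~tr
        sub = DesignMatrix(
            design.X[tr], design.y[tr], list(design.column_labels)
        )
        Xs, yc, y_mean, means, sds, keep = _standardize(sub)
        G = Xs.T @ Xs
        c = Xs.T @ yc
        Xte = design.X[te][:, keep]
        Xte_s = (Xte - means[keep]) / sds[keep]
        yte = design.y[te]
        beta = np.zeros(Xs.shape[1])
        last_ratio = None
        for i, (m, lam1, lam2) in enumerate(cells):
            if m != last_ratio:
                beta[:] = 0.0  # new ladder: restart from the all-zero top
                last_ratio = m
            sweeps = _cd_kernel(G, c, float(lam1), float(lam2), beta, tol, max_sweeps)
            if sweeps < 0:
                raise ConvergenceError("CV cell did not converge", beta.copy())
            pred = y_mean + Xte_s @ beta
            sse[i] += float(((yte - pred) ** 2).sum())

    mse = sse / design.n
    best = mse.min()
    tied = [i for i, v in enumerate(mse) if v <= best + 1e-12]
    chosen = max(tied, key=lambda i: (cells[i][1], cells[i][2]))
    grid_df = pd.DataFrame(
        cells, columns=["mixing_ratio", "lam1", "lam2"]
    ).assign(mean_cv_mse=mse)
    return CVResult(
        grid=grid_df,
        lam1=float(cells[chosen][1]),
        lam2=float(cells[chosen][2]),
        fold_assignments=folds,
        seed=seed,
    )


def fit_cv(
    design: DesignMatrix, n_folds: int = 10, seed: int = 0, grid=None
):
    """Convenience: CV penalty selection followed by a full-data refit."""
    cv = cross_validate_penalties(design, n_folds=n_folds, grid=grid, seed=seed)
    model = fit_elastic_net(design, cv.lam1, cv.lam2)
    return model, cv
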