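"""Feature normalization, Spearman redundancy pruning, and LASSO selection.

The selection chain reduces a subjects x features radiomics table to the
small sparse set the rad-score is built from:

1. per-feature min-max scaling to [0, 1] using *training-cohort* statistics
   (validation data are transformed with the same parameters and clipped);
2. greedy redundancy pruning: while any retained pair has Spearman
   |rho| > 0.9, drop — from the currently worst pair — the member with the
   larger mean |rho| against all other retained features (ties broken by
   dropping the lexicographically later name), which is deterministic and
   order-independent;
3. LASSO on the binary group label as a continuous response,
   ``(1/2n) ||y - b0 - X b||^2 + lambda ||b||_1``, with the penalty chosen by
   10-fold label-stratified cross-validation over a 100-point log grid from
   ``lambda_max = max_j |X_j^T (y - ybar)| / n`` down to 1e-3 lambda_max.
   Features with non-zero coefficients at the selected penalty are the
   "valuable predictors".

Normalization, pruning and selection all see the training cohort only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LassoCV
from sklearn.model_selection import StratifiedKFold

__all__ = [
    "NormalizationParams",
    "SelectionResult",
    "normalize_features",
    "spearman_prune",
    "lasso_cv",
    "select_features",
]


@dataclass
class NormalizationParams:
    feature_min: pd.Series
    feature_max: pd.Series

    @property
    def names(self) -> list[str]:
        return list(self.feature_min.index)


@dataclass
class SelectionResult:
    retained: list[str]                 # survivors of redundancy pruning
    selected: list[str]                 # non-zero LASSO coefficients
    weights: dict[str, float]
    intercept: float
    lambda_selected: float
    cv_curve: list[tuple[float, float, float]]  # (lambda, mean CV MSE, SE)

    def __post_init__(self) -> None:
        assert set(self.selected) <= set(self.retained)
        assert all(self.weights[n] != 0 for n in self.selected)


def normalize_features(
    table: pd.DataFrame, params: NormalizationParams | None = None
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Min-max scale each feature to [0, 1].

    Without ``params`` the statistics are fit on ``table`` (the training
    cohort) and constant features are dropped with a warning; with ``params``
    the stored statistics are applied and the result clipped to [0, 1]
    (validation-cohort transfer).
    """
    if params is None:
        lo = table.min(axis=0)
        hi = table.max(axis=0)
        constant = hi == lo
        if constant.any():
            warnings.warn(
                f"normalize_features: dropping {int(constant.sum())} "
                "constant feature(s)"
            )
            table = table.loc[:, ~constant]
            lo, hi = lo[~constant], hi[~constant]
        params = NormalizationParams(lo, hi)
        return (table - lo) / (hi - lo), params
    table = table[params.names]
    out = (table - params.feature_min) / (
        params.feature_max - params.feature_min
    )
    return out.clip(0.0, 1.0), params


def spearman_prune(table: pd.DataFrame, threshold: float = 0.9) -> list[str]:
    """Greedy redundancy pruning at Spearman |rho| > threshold.

    Returns the retained feature names (original column order).  From the
    currently highest-|rho| offending pair, the member with the larger mean
    |rho| to all currently retained features is dropped; exact ties drop the
    lexicographically later name.
    """
    if len(table) < 3:
        raise ValueError("spearman_prune needs at least 3 subjects")
    names = list(table.columns)
    p = len(names)
    if p < 2:
        return names
    ranks = stats.rankdata(table.to_numpy(dtype=float), axis=0)
    with np.errstate(invalid="ignore"):
        rho = np.abs(np.corrcoef(ranks, rowvar=False))
    rho = np.nan_to_num(rho, nan=0.0)
    rho = 0.5 * (rho + rho.T)  # BLAS matmul is not exactly symmetric
    np.fill_diagonal(rho, 0.0)

    alive = np.ones(p, dtype=bool)
    while True:
        sub = np.where(alive)[0]
        if len(sub) < 2:
            break
        block = rho[np.ix_(sub, sub)]
        top = block.max()
        if top <= threshold:
            break
        # among exactly tied worst pairs, pick the lexicographically first
        # name pair so the outcome is column-order independent
        ii, jj = np.where(block == top)
        cands = [
            tuple(sorted((names[sub[i]], names[sub[j]])))
            for i, j in zip(ii, jj)
            if i < j
        ]
        na, nb = min(cands)
        a, b = names.index(na), names.index(nb)
        # mean |rho| against the currently retained set; summing in sorted
        # order keeps the comparison independent of the input column order
        mean_a = float(np.sort(rho[a, alive]).sum())
        mean_b = float(np.sort(rho[b, alive]).sum())
        if mean_a > mean_b:
            drop = a
        elif mean_b > mean_a:
            drop = b
        else:
            drop = a if names[a] > names[b] else b
        alive[drop] = False
    return [names[i] for i in range(p) if alive[i]]


def _lambda_grid(X: np.ndarray, y: np.ndarray, n_points: int = 100) -> np.ndarray:
    n = len(y)
    lam_max = np.max(np.abs(X.T @ (y - y.mean()))) / n
    if lam_max <= 0:
        raise ValueError("degenerate design: lambda_max is 0")
    return np.geomspace(lam_max, 1e-3 * lam_max, n_points)


def lasso_cv(
    X: pd.DataFrame,
    y: np.ndarray,
    n_folds: int = 10,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> SelectionResult:
    """L1-penalized least squares with cross-validated penalty choice.

    Folds are stratified by the binary label with a fixed seed; the penalty
    minimizing mean CV squared error is refit on the full table.
    """
    names = list(X.columns)
    Xm = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("labels must contain both classes")
    if len(y) < n_folds:
        raise ValueError("fewer subjects than CV folds")
    if lambda_grid is None:
        lambda_grid = _lambda_grid(Xm, y)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(Xm, y.astype(int)))
    model = LassoCV(alphas=lambda_grid, cv=folds, max_iter=50_000, tol=1e-8)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign convergence chatter
        model.fit(Xm, y)

    # mse_path_ rows follow model.alphas_ (descending), columns are folds
    order = np.argsort(model.alphas_)[::-1]
    alphas = model.alphas_[order]
    mse = model.mse_path_
    if mse.ndim == 1:  # single-penalty grid
        mse = mse[None, :]
    mse = mse[order]
    mean_mse = mse.mean(axis=1)
    se_mse = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
    cv_curve = [
        (float(a), float(m), float(s))
        for a, m, s in zip(alphas, mean_mse, se_mse)
    ]
    weights = {n: float(w) for n, w in zip(names, model.coef_)}
    selected = [n for n in names if weights[n] != 0.0]
    return SelectionResult(
        retained=names,
        selected=selected,
        weights=weights,
        intercept=float(model.intercept_),
        lambda_selected=float(model.alpha_),
        cv_curve=cv_curve,
    )


def select_features(
    train: pd.DataFrame,
    y_train: np.ndarray,
    prune_threshold: float = 0.9,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[SelectionResult, NormalizationParams]:
    """Full selection chain on the training cohort: normalize, prune, LASSO.

    If the CV-optimal penalty zeroes every coefficient (a possible outcome on
    null data), the smallest-CV-error penalty with at least one non-zero
    coefficient is used instead, so downstream models always have >= 1
    feature; the returned ``lambda_selected`` reflects the penalty used.
    """
    norm, params = normalize_features(train)
    retained = spearman_prune(norm, prune_threshold)
    result = lasso_cv(norm[retained], y_train, n_folds=n_folds, seed=seed)
    if not result.selected:
        result = _fallback_nonempty(norm[retained], y_train, result, seed)
    result.retained = retained
    return result, params


def _fallback_nonempty(
    X: pd.DataFrame, y: np.ndarray, result: SelectionResult, seed: int
) -> SelectionResult:
    from sklearn.linear_model import Lasso

    Xm = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    for lam, _, _ in sorted(result.cv_curve, key=lambda t: t[1]):
        fit = Lasso(alpha=lam, max_iter=50_000, tol=1e-8).fit(Xm, y)
        if np.any(fit.coef_ != 0):
            weights = {n: float(w) for n, w in zip(X.columns, fit.coef_)}
            return SelectionResult(
                retained=list(X.columns),
                selected=[n for n, w in weights.items() if w != 0.0],
                weights=weights,
                intercept=float(fit.intercept_),
                lambda_selected=float(lam),
                cv_curve=result.cv_curve,
            )
    warnings.warn("LASSO selected no features at any penalty")
    return result
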