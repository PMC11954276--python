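"""Rad-score and logistic-regression classifiers with evaluation statistics.

The positive class throughout is the cognitively impaired group (CI = 1);
a subject is called positive when its score exceeds the operating threshold.
The module covers:

* stratified 7:3 cohort splitting,
* SMOTE minority oversampling (training cohort only, after the split),
* the rad-score (linear combination of LASSO-selected features) with a
  Youden-index operating threshold chosen on the training cohort,
* ROC/AUC (Mann-Whitney convention, ties count one half), accuracy /
  sensitivity / specificity with Wilson confidence intervals, DeLong AUC
  variance and paired AUC comparison, decision-curve net benefit, and exact
  linear-model SHAP attributions,
* the sweep over all 15 non-empty subsets of {ALFF, DC, ReHo, VMHC}.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors
from statsmodels.stats.proportion import proportion_confint

from .feature_selection import (
    NormalizationParams,
    SelectionResult,
    normalize_features,
    select_features,
)

__all__ = [
    "RadScoreModel",
    "EvalReport",
    "split_cohort",
    "smote",
    "radscore",
    "roc_auc",
    "youden_threshold",
    "evaluate",
    "fit_logistic",
    "delong_test",
    "delong_ci",
    "decision_curve",
    "linear_shap",
    "combination_sweep",
    "all_combinations",
    "METRIC_LABELS",
]

METRIC_LABELS = {"alff": "ALFF", "dc": "DC", "reho": "ReHo", "vmhc": "VMHC"}


@dataclass
class RadScoreModel:
    feature_names: list[str]
    weights: np.ndarray
    intercept: float
    youden_threshold: float  # chosen on the training cohort only


@dataclass
class EvalReport:
    auc: float
    auc_ci95: tuple[float, float]
    acc: float
    acc_ci95: tuple[float, float]
    sen: float
    sen_ci95: tuple[float, float]
    spe: float
    spe_ci95: tuple[float, float]
    confusion: np.ndarray  # [[TN, FP], [FN, TP]]
    roc_points: list[tuple[float, float, float]]
    net_benefit: list[tuple[float, float]] = field(default_factory=list)
    shap: np.ndarray | None = None


# --------------------------------------------------------------------------
# cohort handling
# --------------------------------------------------------------------------

def split_cohort(labels: np.ndarray, ratio: float = 0.7, seed: int = 0):
    """Stratified train/validation split; returns (train_idx, val_idx)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 subjects per class")
    idx = np.arange(len(y))
    tr, va = train_test_split(
        idx, train_size=ratio, stratify=y, random_state=seed
    )
    for part in (tr, va):
        if len(np.unique(y[part])) < 2:
            raise ValueError("a class is absent from one side of the split")
    return np.sort(tr), np.sort(va)


def smote(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to exact class balance.

    Each synthetic sample is ``x + u (x_nn - x)`` with ``u ~ U(0, 1)`` and
    ``x_nn`` one of the ``k`` nearest minority neighbours (k is capped at
    minority size - 1).  Already balanced input is returned unchanged.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("smote expects exactly 2 classes")
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = classes[np.argmin(counts)]
    n_needed = int(abs(counts[0] - counts[1]))
    Xmin = X[y == minority]
    if len(Xmin) < 2:
        raise ValueError("minority class needs at least 2 samples")
    k = min(k, len(Xmin) - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, neigh = nn.kneighbors(Xmin)  # column 0 is the point itself
    rng = np.random.default_rng(seed)
    base = rng.integers(0, len(Xmin), size=n_needed)
    pick = rng.integers(1, k + 1, size=n_needed)
    u = rng.uniform(0.0, 1.0, size=(n_needed, 1))
    x0 = Xmin[base]
    x1 = Xmin[neigh[base, pick]]
    synth = x0 + u * (x1 - x0)
    return (
        np.vstack([X, synth]),
        np.concatenate([y, np.full(n_needed, minority, dtype=y.dtype)]),
    )


# --------------------------------------------------------------------------
# rad-score
# --------------------------------------------------------------------------

def radscore(x, model: RadScoreModel) -> float | np.ndarray:
    """Linear combination ``intercept + sum_j w_j x_j`` of the selected
    features; accepts a mapping/Series (one subject) or DataFrame (many)."""
    if isinstance(x, pd.DataFrame):
        missing = [n for n in model.feature_names if n not in x.columns]
        if missing:
            raise KeyError(f"missing feature(s): {missing}")
        vals = x[model.feature_names].to_numpy(dtype=float)
        return model.intercept + vals @ model.weights
    missing = [n for n in model.feature_names if n not in x]
    if missing:
        raise KeyError(f"missing feature(s): {missing}")
    vals = np.array([float(x[n]) for n in model.feature_names])
    return float(model.intercept + vals @ model.weights)


def build_radscore_model(
    selection: SelectionResult, X_train: pd.DataFrame, y_train: np.ndarray
) -> RadScoreModel:
    """Rad-score from a LASSO selection, thresholded by Youden on training."""
    names = selection.selected
    model = RadScoreModel(
        feature_names=names,
        weights=np.array([selection.weights[n] for n in names]),
        intercept=selection.intercept,
        youden_threshold=0.0,
    )
    scores = radscore(X_train, model)
    model.youden_threshold = youden_threshold(scores, y_train)
    return model


# --------------------------------------------------------------------------
# ROC / thresholds / metrics
# --------------------------------------------------------------------------

def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """ROC points over all distinct thresholds and the Mann-Whitney AUC.

    ``AUC = U / (n1 n0)`` with tied score pairs counted one half — identical
    to the trapezoidal area under the empirical ROC curve.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pos = scores[y == 1]
    neg = scores[y == 0]
    ranks = stats.rankdata(scores)
    auc = (ranks[y == 1].sum() - len(pos) * (len(pos) + 1) / 2) / (
        len(pos) * len(neg)
    )
    fpr, tpr, thr = roc_curve(y, scores)
    points = [(float(f), float(t), float(h)) for f, t, h in zip(fpr, tpr, thr)]
    return points, float(auc)


def youden_threshold(scores: np.ndarray, labels: np.ndarray) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1 under the rule
    ``score > threshold`` => positive.

    Candidates are the distinct score values; ties on J prefer the higher
    sensitivity, then the lower threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    best = None
    for t in np.unique(scores):
        pred = scores > t
        sen = (pred & (y == 1)).sum() / n_pos
        spe = (~pred & (y == 0)).sum() / n_neg
        j = sen + spe - 1.0
        key = (j, sen, -t)  # maximize J, then sensitivity, then prefer low t
        if best is None or key > best[0]:
            best = (key, float(t))
    return best[1]


def _wilson(k: int, n: int) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def evaluate(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> EvalReport:
    """Accuracy / sensitivity / specificity (Wilson 95 % CIs), confusion
    table, ROC points and DeLong AUC confidence interval at one threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    pred = (scores > threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = len(y)
    points, auc = roc_auc(scores, y)
    return EvalReport(
        auc=auc,
        auc_ci95=delong_ci(scores, y),
        acc=(tp + tn) / n,
        acc_ci95=_wilson(tp + tn, n),
        sen=tp / (tp + fn) if tp + fn else 0.0,
        sen_ci95=_wilson(tp, tp + fn),
        spe=tn / (tn + fp) if tn + fp else 0.0,
        spe_ci95=_wilson(tn, tn + fp),
        confusion=np.array([[tn, fp], [fn, tp]]),
        roc_points=points,
    )


# --------------------------------------------------------------------------
# logistic regression
# --------------------------------------------------------------------------

RIDGE_ALPHA = 1e-4  # tiny L2 term keeping separable fits finite


def fit_logistic(
    X: np.ndarray, y: np.ndarray, seed: int = 0
) -> tuple[np.ndarray, float]:
    """Maximum-likelihood logistic regression with a tiny ridge penalty.

    Minimizes ``sum_i CE_i + (alpha/2) ||w||^2`` with alpha = 1e-4 (intercept
    unpenalized).  Returns (weights, intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.any(np.ptp(X, axis=0) == 0):
        raise ValueError("constant feature column in logistic design")
    model = LogisticRegression(
        C=1.0 / RIDGE_ALPHA,
        solver="lbfgs",
        max_iter=20_000,
        tol=1e-12,
        random_state=seed,
    )
    model.fit(X, y)
    if model.n_iter_[0] >= 20_000:
        raise RuntimeError(
            f"logistic regression did not converge ({model.n_iter_[0]} iters)"
        )
    return model.coef_.ravel().copy(), float(model.intercept_[0])


def predict_logistic(X: np.ndarray, weights: np.ndarray, intercept: float):
    logits = np.asarray(X, dtype=float) @ weights + intercept
    return 1.0 / (1.0 + np.exp(-logits))


# --------------------------------------------------------------------------
# DeLong machinery
# --------------------------------------------------------------------------

def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, y: np.ndarray):
    """Placement values V10 (per positive) and V01 (per negative)."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = len(pos), len(neg)
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    v10 = (tz[:m] - tx) / n
    v01 = 1.0 - (tz[m:] - ty) / m
    auc = v10.mean()
    return auc, v10, v01


def delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    auc, v10, v01 = _structural_components(scores, y)
    return float(np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01))


def delong_ci(scores: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """DeLong 95 % confidence interval for a single AUC, clipped to [0, 1]."""
    y = np.asarray(y).astype(int)
    scores = np.asarray(scores, dtype=float)
    auc, v10, v01 = _structural_components(scores, y)
    se = np.sqrt(
        np.var(v10, ddof=1) / len(v10) + np.var(v01, ddof=1) / len(v01)
    )
    return (
        float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0)),
        float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0)),
    )


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float, float]:
    """Paired DeLong comparison of two correlated AUCs on the same subjects.

    Returns (auc_a, auc_b, z, two-sided p).  A degenerate variance (e.g.
    identical score vectors) yields p = 1 with a warning.
    """
    y = np.asarray(labels).astype(int)
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != y.shape:
        raise ValueError("paired scores and labels must have equal length")
    auc_a, v10_a, v01_a = _structural_components(a, y)
    auc_b, v10_b, v01_b = _structural_components(b, y)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.vstack([v10_a, v10_b]))
    s01 = np.cov(np.vstack([v01_a, v01_b]))
    var = s10 / m + s01 / n
    var_diff = var[0, 0] + var[1, 1] - 2.0 * var[0, 1]
    if var_diff <= 0:
        warnings.warn("delong_test: degenerate variance, p set to 1")
        return float(auc_a), float(auc_b), 0.0, 1.0
    z = (auc_a - auc_b) / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(auc_a), float(auc_b), float(z), float(p)


# --------------------------------------------------------------------------
# decision curve analysis
# --------------------------------------------------------------------------

def decision_curve(
    probabilities: np.ndarray,
    labels: np.ndarray,
    thresholds: np.ndarray | None = None,
):
    """Net benefit of the classifier plus treat-all / treat-none references.

    ``NB(pt) = TP/n - FP/n * pt / (1 - pt)`` calling positive when the
    predicted probability exceeds pt.  Returns a DataFrame with columns
    (threshold, net_benefit, treat_all, treat_none).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if thresholds is None:
        thresholds = np.linspace(0.01, 0.99, 99)
    n = len(y)
    prevalence = y.mean()
    rows = []
    for pt in thresholds:
        pred = p > pt
        tp = int((pred & (y == 1)).sum())
        fp = int((pred & (y == 0)).sum())
        odds = pt / (1.0 - pt)
        rows.append(
            (
                float(pt),
                tp / n - fp / n * odds,
                prevalence - (1.0 - prevalence) * odds,
                0.0,
            )
        )
    return pd.DataFrame(
        rows, columns=["threshold", "net_benefit", "treat_all", "treat_none"]
    )


# --------------------------------------------------------------------------
# linear SHAP
# --------------------------------------------------------------------------

def linear_shap(
    weights: np.ndarray, X: np.ndarray, background_means: np.ndarray
) -> np.ndarray:
    """Exact Shapley attributions of a linear (log-odds) model under feature
    independence: ``phi_ij = w_j (x_ij - mean_j)``."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.asarray(weights, dtype=float)[None, :] * (
        X - np.asarray(background_means, dtype=float)[None, :]
    )


# --------------------------------------------------------------------------
# combination sweep
# --------------------------------------------------------------------------

def all_combinations(metrics=("alff", "dc", "reho", "vmhc")):
    """The 15 non-empty subsets of the four derivative metrics."""
    out = []
    for r in range(1, len(metrics) + 1):
        out.extend(itertools.combinations(metrics, r))
    return out


def _concat_tables(tables: dict[str, pd.DataFrame], combo) -> pd.DataFrame:
    parts = []
    for metric in combo:
        t = tables[metric].copy()
        t.columns = [f"{METRIC_LABELS[metric]}_{c}" for c in t.columns]
        parts.append(t)
    return pd.concat(parts, axis=1)


@dataclass
class ComboResult:
    combo: tuple[str, ...]
    selection: SelectionResult
    rad_model: RadScoreModel
    lr_weights: np.ndarray
    lr_intercept: float
    rad_train: EvalReport
    rad_validation: EvalReport
    lr_train: EvalReport
    lr_validation: EvalReport
    rad_scores_validation: np.ndarray
    lr_prob_validation: np.ndarray


def evaluate_combination(
    tables: dict[str, pd.DataFrame],
    labels: np.ndarray,
    combo,
    train_idx: np.ndarray,
    val_idx: np.ndarray,
    seed: int = 0,
    prune_threshold: float = 0.9,
    n_folds: int = 10,
    smote_k: int = 5,
) -> ComboResult:
    """Selection, rad-score and LR pipeline for one metric subset on a fixed
    split.  Only training rows touch normalization, pruning, LASSO, the
    Youden threshold, SMOTE and the LR fit."""
    full = _concat_tables(tables, combo)
    y = np.asarray(labels).astype(int)
    train = full.iloc[train_idx]
    val = full.iloc[val_idx]
    y_tr, y_va = y[train_idx], y[val_idx]

    # stratified CV cannot have more folds than the smaller class
    n_folds_eff = max(2, min(n_folds, int(np.bincount(y_tr).min())))
    selection, norm_params = select_features(
        train, y_tr, prune_threshold=prune_threshold,
        n_folds=n_folds_eff, seed=seed,
    )
    Xtr, _ = normalize_features(train, norm_params)
    Xva, _ = normalize_features(val, norm_params)

    rad_model = build_radscore_model(selection, Xtr, y_tr)
    rad_tr = np.asarray(radscore(Xtr, rad_model))
    rad_va = np.asarray(radscore(Xva, rad_model))

    sel = selection.selected
    Xtr_sel = Xtr[sel].to_numpy(dtype=float)
    Xva_sel = Xva[sel].to_numpy(dtype=float)
    Xb, yb = smote(Xtr_sel, y_tr, k=smote_k, seed=seed)
    # SMOTE interpolation can leave a column constant only if it already was
    keep = np.ptp(Xb, axis=0) > 0
    w = np.zeros(Xb.shape[1])
    w[keep], b0 = fit_logistic(Xb[:, keep], yb, seed=seed)
    prob_tr = predict_logistic(Xtr_sel, w, b0)
    prob_va = predict_logistic(Xva_sel, w, b0)

    rep_rad_tr = evaluate(rad_tr, y_tr, rad_model.youden_threshold)
    rep_rad_va = evaluate(rad_va, y_va, rad_model.youden_threshold)
    rep_lr_tr = evaluate(prob_tr, y_tr, 0.5)
    rep_lr_va = evaluate(prob_va, y_va, 0.5)
    rep_lr_va.net_benefit = list(
        decision_curve(prob_va, y_va)[["threshold", "net_benefit"]]
        .itertuples(index=False, name=None)
    )
    rep_lr_va.shap = linear_shap(w, Xva_sel, Xtr_sel.mean(axis=0))
    return ComboResult(
        combo=tuple(combo),
        selection=selection,
        rad_model=rad_model,
        lr_weights=w,
        lr_intercept=b0,
        rad_train=rep_rad_tr,
        rad_validation=rep_rad_va,
        lr_train=rep_lr_tr,
        lr_validation=rep_lr_va,
        rad_scores_validation=rad_va,
        lr_prob_validation=prob_va,
    )


def combination_sweep(
    tables: dict[str, pd.DataFrame],
    labels: np.ndarray,
    seed: int = 0,
    ratio: float = 0.7,
    **kwargs,
) -> dict[tuple[str, ...], ComboResult]:
    """All 15 metric-subset pipelines on one shared stratified split."""
    y = np.asarray(labels).astype(int)
    train_idx, val_idx = split_cohort(y, ratio=ratio, seed=seed)
    return {
        combo: evaluate_combination(
            tables, y, combo, train_idx, val_idx, seed=seed, **kwargs
        )
        for combo in all_combinations(tuple(tables.keys()))
    }
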