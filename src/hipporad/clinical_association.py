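"""Clinical-association statistics: group comparisons and age-adjusted
partial correlations with Bonferroni correction.

Partial correlation is the Pearson correlation of the residuals of the two
variables after least-squares regression on the covariates (plus intercept);
its p-value uses ``t = r sqrt((n - 2 - k) / (1 - r^2))`` with ``k``
covariates, two-sided.  The Bonferroni family size defaults to 7 tests per
feature-scale family (configurable).

Group comparisons choose the test by variable type: chi-square (no
continuity correction) for categorical variables; for quantitative ones a
Shapiro-Wilk normality gate (alpha = 0.05 in both groups) selects the
two-sample t test, otherwise the Mann-Whitney U test.  All two-sided.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AssociationResult",
    "partial_correlation",
    "bonferroni",
    "group_compare",
    "associate",
    "DEFAULT_SCALES",
]

DEFAULT_SCALES = (
    "moca", "updrs3", "nmss", "pdq39", "hama", "hamd",
    "bmi", "education", "duration",
)


@dataclass
class AssociationResult:
    feature: str
    scale: str
    group: str
    r_partial: float
    p_raw: float
    p_bonferroni: float
    n_tests: int
    significant: bool


def _residualize(v: np.ndarray, Z: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given the covariate columns."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.atleast_2d(np.asarray(covariates, dtype=float))
    if cov.shape[0] != len(x):
        cov = cov.T
    n, k = cov.shape
    if len(x) != n or len(y) != n:
        raise ValueError("x, y and covariates must have equal length")
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    Z = np.column_stack([np.ones(n), cov])
    rx = _residualize(x, Z)
    ry = _residualize(y, Z)
    # a variable that is (numerically) an exact linear function of the
    # covariates has no residual variance left to correlate
    if (
        rx.std() <= 1e-10 * max(1.0, x.std())
        or ry.std() <= 1e-10 * max(1.0, y.std())
    ):
        raise ValueError("zero residual variance after covariate adjustment")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    r_ = np.clip(r, -0.999999999999, 0.999999999999)
    t = r_ * np.sqrt(df / (1.0 - r_ * r_))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def bonferroni(p_raw: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value: min(1, p * n)."""
    if not 0.0 <= p_raw <= 1.0:
        raise ValueError("p_raw must lie in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_raw * n_tests)


def group_compare(values, groups, kind: str = "auto"):
    """Two-group comparison; returns (statistic, p, test_name).

    kind: "categorical" (chi-square on the contingency table),
    "quantitative" (normality-gated t vs Mann-Whitney), "auto"
    (categorical iff values are non-numeric), or an explicit "ttest" /
    "mannwhitney" override that skips the gate.
    """
    values = np.asarray(values)
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    if kind == "auto":
        kind = (
            "categorical"
            if values.dtype.kind in "OUSb"
            else "quantitative"
        )
    if kind == "categorical":
        table = pd.crosstab(pd.Series(groups), pd.Series(values)).to_numpy()
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return float(stat), float(p), "chi-square"
    a = values[groups == levels[0]].astype(float)
    b = values[groups == levels[1]].astype(float)
    if kind == "quantitative":
        normal = all(
            len(np.unique(g)) > 2 and stats.shapiro(g).pvalue > 0.05
            for g in (a, b)
        )
        kind = "ttest" if normal else "mannwhitney"
    if kind == "ttest":
        stat, p = stats.ttest_ind(a, b, equal_var=True)
        return float(stat), float(p), "t-test"
    if kind != "mannwhitney":
        raise ValueError(f"unknown comparison kind {kind!r}")
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p), "mann-whitney"


def associate(
    features: pd.DataFrame,
    clinical: pd.DataFrame,
    feature_names: list[str] | None = None,
    scales=DEFAULT_SCALES,
    covariate: str = "age",
    n_tests: int = 7,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Age-adjusted partial correlations feature x scale within each group.

    ``features`` and ``clinical`` must be row-aligned (same subjects, same
    order); ``clinical`` needs 'group' and the covariate column.  Returns a
    long-format table of AssociationResult rows (heatmap-ready).  Pairs with
    degenerate residuals are skipped.
    """
    if feature_names is None:
        feature_names = list(features.columns)
    rows = []
    for grp in ("CI", "CP"):
        sel = (clinical["group"] == grp).to_numpy()
        if sel.sum() <= 3:
            continue
        cov = clinical.loc[sel, covariate].to_numpy(dtype=float)
        for feat in feature_names:
            fv = features.loc[sel, feat].to_numpy(dtype=float)
            for scale in scales:
                sv = clinical.loc[sel, scale].to_numpy(dtype=float)
                try:
                    r, p = partial_correlation(fv, sv, cov)
                except ValueError:
                    continue
                p_adj = bonferroni(p, n_tests)
                rows.append(
                    AssociationResult(
                        feature=feat, scale=scale, group=grp,
                        r_partial=r, p_raw=p, p_bonferroni=p_adj,
                        n_tests=n_tests, significant=p_adj < alpha,
                    )
                )
    return pd.DataFrame([vars(r) for r in rows])
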