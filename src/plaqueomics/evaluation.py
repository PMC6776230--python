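"""Histogram baselines, ROC/AUC with DeLong inference, and chi-square checks.

The two histogram-based plaque markers are the per-cross-section area of low
attenuation (voxels < 30 HU) and the mean Hounsfield unit of the lesion.
Model and baseline scores are compared on a common validation set with
DeLong's nonparametric estimator of the variance and covariance of
correlated AUCs, which yields confidence intervals and a paired two-sided
z-test for the difference of two ROC curves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.linear_model import LogisticRegression

__all__ = [
    "ROCResult",
    "DeLongComparison",
    "low_attenuation_area",
    "mean_hu",
    "univariate_logistic_baseline",
    "auc_delong",
    "compare_delong",
    "chi_square_balance",
]

LOW_ATTENUATION_THRESHOLD_HU = 30.0


@dataclass(frozen=True)
class ROCResult:
    """AUC of one score vector with DeLong variance and 95% CI."""

    auc: float
    variance: float
    ci: tuple[float, float]
    scores: np.ndarray
    labels: np.ndarray


@dataclass(frozen=True)
class DeLongComparison:
    """Paired DeLong test between two correlated ROC curves."""

    auc_difference: float
    variance: float
    z: float
    p_value: float
    degenerate: bool = False


def low_attenuation_area(lesion, threshold: float = LOW_ATTENUATION_THRESHOLD_HU,
                         ) -> float:
    """Per-cross-section area (mm^2) of plaque voxels strictly below
    ``threshold`` HU.

    Computed as (count of voxels < threshold) x in-plane pixel area, divided
    by the number of z-layers the mask spans, i.e. the mean per-layer
    low-attenuation area of the slab.
    """
    values = np.asarray(lesion.values)
    n_low = int((values < threshold).sum())
    sx, sy, _ = lesion.spacing_mm
    n_layers = len(np.unique(lesion.coords[:, 2]))
    return n_low * sx * sy / n_layers


def mean_hu(lesion) -> float:
    """Arithmetic mean Hounsfield unit of the masked voxels."""
    return float(np.mean(lesion.values))


def _delong_placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong structural components (per-positive V10, per-negative V01)
    and the tie-corrected AUC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc = float(v10.mean())
    return auc, v10, v01


def auc_delong(scores, labels) -> ROCResult:
    """AUC (Mann-Whitney, ties counted 0.5) with DeLong variance and a
    normal-approximation 95% CI clipped to [0, 1]."""
    auc, v10, v01 = _delong_placements(scores, labels)
    m, n = len(v10), len(v01)
    var10 = v10.var(ddof=1) if m > 1 else 0.0
    var01 = v01.var(ddof=1) if n > 1 else 0.0
    variance = float(var10 / m + var01 / n)
    se = np.sqrt(max(variance, 0.0))
    ci = (float(np.clip(auc - 1.959963984540054 * se, 0.0, 1.0)),
          float(np.clip(auc + 1.959963984540054 * se, 0.0, 1.0)))
    return ROCResult(auc=auc, variance=variance, ci=ci,
                     scores=np.asarray(scores, dtype=np.float64),
                     labels=np.asarray(labels).astype(int))


def compare_delong(result_a: ROCResult, result_b: ROCResult) -> DeLongComparison:
    """Paired DeLong test for two score vectors on the same labels.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov), two-sided normal p.
    A zero variance of the difference (e.g. rank-identical scores) is
    flagged degenerate with an undefined p-value.
    """
    if not np.array_equal(result_a.labels, result_b.labels):
        raise ValueError("paired comparison requires identical labels")
    auc_a, v10_a, v01_a = _delong_placements(result_a.scores, result_a.labels)
    auc_b, v10_b, v01_b = _delong_placements(result_b.scores, result_b.labels)
    m, n = len(v10_a), len(v01_a)
    var_a = (v10_a.var(ddof=1) / m if m > 1 else 0.0) + \
            (v01_a.var(ddof=1) / n if n > 1 else 0.0)
    var_b = (v10_b.var(ddof=1) / m if m > 1 else 0.0) + \
            (v01_b.var(ddof=1) / n if n > 1 else 0.0)
    cov = 0.0
    if m > 1:
        cov += float(np.cov(v10_a, v10_b, ddof=1)[0, 1]) / m
    if n > 1:
        cov += float(np.cov(v01_a, v01_b, ddof=1)[0, 1]) / n
    diff = auc_a - auc_b
    var_diff = var_a + var_b - 2.0 * cov
    if var_diff <= 1e-16:
        return DeLongComparison(auc_difference=float(diff), variance=float(var_diff),
                                z=0.0, p_value=float("nan"), degenerate=True)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return DeLongComparison(auc_difference=float(diff), variance=float(var_diff),
                            z=float(z), p_value=float(p), degenerate=False)


def univariate_logistic_baseline(x_train, y_train, x_validation, y_validation,
                                 categorical: bool = False) -> ROCResult:
    """Fit a logistic model on one predictor (or a 3-level category encoded
    as two indicators) on the training rows, score the validation rows by
    fitted probability, and return the validation ROCResult.

    For a single numeric predictor the logistic map is monotone, so the
    validation AUC equals that of the raw predictor (possibly reflected).
    """
    x_train = np.asarray(x_train)
    x_validation = np.asarray(x_validation)
    if categorical:
        levels = np.unique(np.concatenate([x_train, x_validation]))
        if len(levels) < 2:
            raise ValueError("categorical predictor needs >= 2 levels")
        Xt = (x_train[:, None] == levels[None, 1:]).astype(float)
        Xv = (x_validation[:, None] == levels[None, 1:]).astype(float)
    else:
        Xt = x_train.reshape(-1, 1).astype(float)
        Xv = x_validation.reshape(-1, 1).astype(float)
    model = LogisticRegression(C=1e6, solver="lbfgs", max_iter=5000)
    model.fit(Xt, np.asarray(y_train).astype(int))
    scores = model.predict_proba(Xv)[:, 1]
    return auc_delong(scores, y_validation)


def chi_square_balance(table) -> tuple[float, float]:
    """Pearson chi-square test (no continuity correction) on a 2D count
    table, e.g. category distribution across the train/validation split.

    Rows or columns with zero margin are dropped (with a warning) before
    testing.
    """
    import warnings

    table = np.asarray(table, dtype=np.float64)
    if table.ndim != 2:
        raise ValueError("expected a 2D count table")
    row_ok = table.sum(axis=1) > 0
    col_ok = table.sum(axis=0) > 0
    if not row_ok.all() or not col_ok.all():
        warnings.warn("dropping zero-margin rows/columns from chi-square table")
        table = table[np.ix_(row_ok, col_ok)]
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("chi-square table needs >= 2 non-empty rows and columns")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(stat), float(p)
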