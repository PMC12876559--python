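"""Agreement and classification metrics for model evaluation.

Includes the identity-line coefficient of determination R^2_{y=x} (residuals
about y = x, not about a fitted line), RMSE with the predictive-sigma
calibration ratio, Bland-Altman limits of agreement, FFR numerical/binary
agreement at the 0.80 ischemia threshold, and ROC AUC with the DeLong test
for two correlated AUCs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


class MetricError(ValueError):
    """A metric's preconditions are not met (e.g. zero variance)."""


@dataclass(frozen=True)
class MetricsReport:
    """Point-prediction quality plus the uncertainty-calibration ratio."""

    r2_identity: float
    rmse: float
    mean_predictive_sigma: float
    rmse_sigma_ratio: float
    n: int


@dataclass(frozen=True)
class AgreementReport:
    """FFR agreement: numerical tolerance, bias/limits, and classification."""

    within_tol_fraction: float
    bias: float
    loa_low: float
    loa_high: float
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float


def r2_identity(y_true: np.ndarray, y_pred: np.ndarray,
                fitted_line: bool = False) -> float:
    """Coefficient of determination about the identity line y = x.

    With ``fitted_line=True`` the classical R^2 of an OLS line through the
    scatter is returned instead.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise MetricError("need two equal-length arrays of size >= 2")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise MetricError("y_true has zero variance")
    if fitted_line:
        r = stats.pearsonr(y_true, y_pred).statistic
        return float(r ** 2)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    return 1.0 - ss_res / ss_tot


def rmse_and_calibration(y_true: np.ndarray, y_pred: np.ndarray,
                         sigmas: np.ndarray) -> MetricsReport:
    """RMSE, mean predictive sigma and their ratio (overconfidence flag).

    A well-calibrated probabilistic predictor has a ratio near one; ratios
    well above one mean the model underestimates its uncertainty.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    sigmas = np.asarray(sigmas, dtype=float)
    rmse = float(np.sqrt(np.mean((y_true - y_pred) ** 2)))
    mean_sigma = float(np.mean(sigmas))
    ratio = rmse / mean_sigma if mean_sigma > 0 else float("nan")
    return MetricsReport(r2_identity=r2_identity(y_true, y_pred)
                         if y_true.size >= 2 and np.ptp(y_true) > 0
                         else float("nan"),
                         rmse=rmse, mean_predictive_sigma=mean_sigma,
                         rmse_sigma_ratio=ratio, n=y_true.size)


def bland_altman(ref: np.ndarray, pred: np.ndarray
                 ) -> tuple[float, float, float]:
    """Mean bias and the bias +/- 1.96 SD limits of agreement."""
    ref = np.asarray(ref, dtype=float)
    pred = np.asarray(pred, dtype=float)
    if ref.shape != pred.shape or ref.size < 2:
        raise MetricError("need two equal-length arrays of size >= 2")
    d = pred - ref
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def ffr_agreement(ref_ffr: np.ndarray, pred_ffr: np.ndarray,
                  tol: float = 0.02, threshold: float = 0.80
                  ) -> AgreementReport:
    """Numerical and binary agreement of predicted FFR against a reference.

    A case is ischemic (positive) when FFR <= threshold.
    """
    ref = np.asarray(ref_ffr, dtype=float)
    pred = np.asarray(pred_ffr, dtype=float)
    if ref.shape != pred.shape or ref.size == 0:
        raise MetricError("need two equal-length non-empty arrays")
    within = float(np.mean(np.abs(pred - ref) <= tol))
    if ref.size >= 2:
        bias, lo, hi = bland_altman(ref, pred)
    else:
        bias, lo, hi = float(pred - ref), float(pred - ref), float(pred - ref)
    ref_pos = ref <= threshold
    pred_pos = pred <= threshold
    tp = int(np.sum(ref_pos & pred_pos))
    fp = int(np.sum(~ref_pos & pred_pos))
    tn = int(np.sum(~ref_pos & ~pred_pos))
    fn = int(np.sum(ref_pos & ~pred_pos))
    acc = (tp + tn) / ref.size
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return AgreementReport(within_tol_fraction=within, bias=bias,
                           loa_low=lo, loa_high=hi, tp=tp, fp=fp, tn=tn,
                           fn=fn, accuracy=acc, sensitivity=sens,
                           specificity=spec)


def _midrank(x: np.ndarray) -> np.ndarray:
    """Midranks (average ranks for ties), 1-based."""
    return stats.rankdata(x, method="average")


def auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC as the Mann-Whitney statistic with half credit for ties."""
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    m, n = int(labels.sum()), int((~labels).sum())
    if m == 0 or n == 0:
        raise MetricError("both classes must be present")
    ranks = _midrank(scores)
    return float((ranks[labels].sum() - m * (m + 1) / 2) / (m * n))


def roc_auc_delong(labels: np.ndarray, scores_a: np.ndarray,
                   scores_b: np.ndarray
                   ) -> tuple[float, float, float, float]:
    """Paired comparison of two correlated ROC AUCs (DeLong).

    Returns (auc_a, auc_b, delta, two-sided p-value).  The AUC covariance
    uses the structural components V10 (per positive) and V01 (per
    negative) of each classifier.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.sum() == 0 or (~labels).sum() == 0:
        raise MetricError("both classes must be present")
    scores = np.stack([np.asarray(scores_a, dtype=float),
                       np.asarray(scores_b, dtype=float)])
    if scores.shape[1] != labels.size:
        raise MetricError("labels and scores must have equal length")
    pos = scores[:, labels]
    neg = scores[:, ~labels]
    m, n = pos.shape[1], neg.shape[1]
    aucs = np.empty(2)
    v10 = np.empty((2, m))
    v01 = np.empty((2, n))
    for k in range(2):
        all_ranks = _midrank(np.concatenate([pos[k], neg[k]]))
        pos_ranks = _midrank(pos[k])
        neg_ranks = _midrank(neg[k])
        aucs[k] = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
        v10[k] = (all_ranks[:m] - pos_ranks) / n
        v01[k] = 1.0 - (all_ranks[m:] - neg_ranks) / m
    auc_a, auc_b = float(aucs[0]), float(aucs[1])
    delta = auc_a - auc_b
    if m > 1 and n > 1:
        s10 = np.cov(v10)
        s01 = np.cov(v01)
        var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m \
            + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    else:
        var = 0.0
    if var <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return auc_a, auc_b, float(delta), p
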