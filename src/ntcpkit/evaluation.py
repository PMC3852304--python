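"""Model evaluation: Spearman Rs, ROC/AUC, Youden cut-point, calibration.

Discrimination is measured by the area under the ROC curve (trapezoid rule
over all observed prediction thresholds, equal to the Mann-Whitney
concordance probability with ties counted 1/2) and summarised by the
threshold maximising Youden's J = sensitivity + specificity - 1.  Predictive
power is quantified, as in data-driven NTCP modelling practice, by the
Spearman rank correlation between predicted NTCP and the binary outcome.
Calibration uses equal-count bins of patients sorted by predicted risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["ROCResult", "CalibrationBins", "roc_auc", "youden_cutoff", "calibration_bins", "model_rs"]


@dataclass
class ROCResult:
    """ROC curve of a set of risk predictions against a binary outcome.

    ``thresholds`` are the decision cut-offs (predict positive when
    prediction >= threshold), in decreasing order starting with +inf (no
    positives).  ``sensitivity`` and ``specificity`` are aligned with them.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float = np.nan
    youden_j: float = np.nan
    youden_value_on_covariate: float | None = None

    @property
    def fpr(self) -> np.ndarray:
        return 1.0 - self.specificity

    @property
    def tpr(self) -> np.ndarray:
        return self.sensitivity


@dataclass
class CalibrationBins:
    """Equal-count calibration bins (counts differ by at most one)."""

    n_bins: int
    counts: np.ndarray
    mean_predicted: np.ndarray
    observed_rate: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": np.arange(1, self.n_bins + 1),
                "n": self.counts,
                "mean_pred": self.mean_predicted,
                "observed": self.observed_rate,
            }
        )


def _check_binary(outcomes: np.ndarray) -> None:
    if not np.all(np.isin(outcomes, (0, 1))):
        raise ValueError("outcomes must be binary 0/1")
    if outcomes.min() == outcomes.max():
        raise ValueError("both outcome classes must be present")


def roc_auc(predictions, outcomes) -> ROCResult:
    """ROC curve and trapezoid AUC over all unique prediction thresholds.

    Tied predictions contribute a diagonal ROC segment, so the trapezoid
    area equals the concordance probability with ties counted 1/2.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise ValueError("predictions and outcomes must align")
    _check_binary(y)
    n_pos = y.sum()
    n_neg = y.size - n_pos
    order = np.argsort(-p, kind="stable")
    p_sorted, y_sorted = p[order], y[order]
    # cumulative counts at each distinct threshold (predict + when p >= t)
    distinct = np.r_[np.diff(p_sorted) != 0, True]
    tp = np.cumsum(y_sorted)[distinct]
    fp = np.cumsum(1.0 - y_sorted)[distinct]
    thresholds = np.r_[np.inf, p_sorted[distinct]]
    sens = np.r_[0.0, tp / n_pos]
    spec = np.r_[1.0, 1.0 - fp / n_neg]
    auc = float(np.trapezoid(sens, 1.0 - spec))
    roc = ROCResult(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)
    _attach_youden(roc)
    return roc


def _attach_youden(roc: ROCResult) -> None:
    j = roc.sensitivity + roc.specificity - 1.0
    best_j = j.max()
    # ties broken toward higher specificity (more conservative cut-off)
    tied = np.flatnonzero(j >= best_j - 1e-12)
    best = tied[np.argmax(roc.specificity[tied])]
    roc.youden_j = float(j[best])
    roc.youden_threshold = float(roc.thresholds[best])


def youden_cutoff(roc: ROCResult, covariate_values=None, predictions=None) -> float:
    """Threshold maximising Youden's J; ties favour higher specificity.

    When the predictions are a monotone function of a single covariate,
    passing the per-patient ``covariate_values`` and ``predictions`` maps
    the probability threshold back to the covariate scale (the smallest
    covariate value classified as high risk).
    """
    if covariate_values is None:
        return roc.youden_threshold
    if predictions is None:
        raise ValueError("covariate back-mapping needs the per-patient predictions")
    cov = np.asarray(covariate_values, dtype=float)
    p = np.asarray(predictions, dtype=float)
    rho = stats.spearmanr(cov, p).statistic
    if not np.isfinite(rho) or abs(rho) < 1.0 - 1e-9:
        raise ValueError("predictions are not a monotone function of the covariate")
    at_threshold = np.isclose(p, roc.youden_threshold, rtol=0, atol=1e-12)
    value = float(cov[at_threshold][0]) if at_threshold.any() else float(
        cov[np.argmin(np.abs(p - roc.youden_threshold))]
    )
    roc.youden_value_on_covariate = value
    return value


def calibration_bins(predictions, outcomes, n_bins: int = 5) -> CalibrationBins:
    """Split patients into equal-count bins by predicted risk.

    Patients are sorted by prediction (stable sort; ties keep input order)
    and divided into ``n_bins`` groups whose sizes differ by at most one.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if n_bins < 1 or n_bins > p.size // 2:
        raise ValueError(f"n_bins must be in [1, n/2], got {n_bins} for n={p.size}")
    order = np.argsort(p, kind="stable")
    chunks = np.array_split(order, n_bins)
    counts = np.array([len(c) for c in chunks])
    mean_pred = np.array([p[c].mean() for c in chunks])
    observed = np.array([y[c].mean() for c in chunks])
    return CalibrationBins(n_bins=n_bins, counts=counts, mean_predicted=mean_pred, observed_rate=observed)


def model_rs(predictions, outcomes) -> float:
    """Spearman rank correlation between predicted NTCP and outcome.

    Constant predictions are degenerate; the correlation is reported as 0
    with a logged warning.
    """
    p = np.asarray(predictions, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.min() == p.max() or y.min() == y.max():
        logger.warning("degenerate input to model_rs (constant values); returning 0")
        return 0.0
    return float(stats.spearmanr(p, y).statistic)
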