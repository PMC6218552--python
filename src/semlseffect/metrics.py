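"""Test-set evaluation of the outcome models.

Three views of out-of-sample performance: variance explained (R^2) of the
predicted follow-up GDI; a post-hoc classification of whether a limb reaches
GDI >= 80 at follow-up (a gait score within two standard deviations of
typical gait); and the ROC obtained by sweeping the GDI threshold applied to
the predictions, summarized by its trapezoidal AUC.  Evaluation is
unweighted: propensity weights are a training device, not a test statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .propensity import ClassificationRates, classification_rates

__all__ = ["r2", "classify_gdi80", "roc_auc", "EvalReport", "evaluate_predictions"]

GDI_HEALTHY_THRESHOLD = 80.0


def r2(y_true, y_pred) -> float:
    """Variance explained, ``1 - RSS/TSS``; may be negative out of sample."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if len(y_true) < 2:
        raise ValueError("need at least 2 observations")
    tss = float(((y_true - y_true.mean()) ** 2).sum())
    if tss == 0:
        raise ValueError("R^2 undefined: y_true is constant")
    rss = float(((y_true - y_pred) ** 2).sum())
    return 1.0 - rss / tss


def classify_gdi80(y_true, y_pred,
                   threshold_gdi: float = GDI_HEALTHY_THRESHOLD) -> ClassificationRates:
    """Agreement of predicted and actual 'GDI at least 80' labels.

    Both sides are dichotomized at the threshold (>=, 'at least'); returns
    accuracy, sensitivity and specificity of the prediction-derived label
    against the truth-derived one.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    return classification_rates(y_true >= threshold_gdi, y_pred,
                                threshold=threshold_gdi)


def roc_auc(y_true_binary, y_score):
    """ROC over all distinct score thresholds, plus its trapezoidal area.

    Returns ``(roc_points, auc)`` where ``roc_points`` is an (n, 2) array of
    (false positive rate, true positive rate) running from (0, 0) to (1, 1).
    """
    y = np.asarray(y_true_binary).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("ROC undefined: only one class present in y_true")
    fpr, tpr, _ = roc_curve(y, np.asarray(y_score, float),
                            drop_intermediate=False)
    points = np.column_stack([fpr, tpr])
    return points, float(np.trapezoid(tpr, fpr))


@dataclass
class EvalReport:
    """Bundle of test-set metrics for one arm's outcome model."""

    r_squared: float
    accuracy: float
    sensitivity: float
    specificity: float
    roc_points: np.ndarray
    auc: float
    n_evaluated: int

    def to_dict(self) -> dict:
        return {
            "r_squared": self.r_squared,
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "auc": self.auc,
            "n_evaluated": self.n_evaluated,
        }


def evaluate_predictions(y_true, y_pred,
                         threshold_gdi: float = GDI_HEALTHY_THRESHOLD) -> EvalReport:
    """Full test-set report from observed and predicted follow-up GDI."""
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    rates = classify_gdi80(y_true, y_pred, threshold_gdi)
    labels = y_true >= threshold_gdi
    if len(np.unique(labels)) == 2:
        points, auc = roc_auc(labels, y_pred)
    else:  # degenerate test sample: ROC undefined
        points, auc = np.array([[0.0, 0.0], [1.0, 1.0]]), np.nan
    return EvalReport(r_squared=r2(y_true, y_pred),
                      accuracy=rates.accuracy, sensitivity=rates.sensitivity,
                      specificity=rates.specificity,
                      roc_points=points, auc=auc, n_evaluated=len(y_true))
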