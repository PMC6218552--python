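"""Treatment-propensity estimation and inverse-propensity weighting.

In an observational gait-lab cohort, which limbs receive multilevel surgery
is anything but random: more severely affected limbs are far likelier to be
operated.  The propensity score — the probability of receiving surgery given
pre-treatment characteristics — is estimated here with a random forest
(100 trees, classes rebalanced to 50/50 priors), and each limb is then
weighted by the inverse probability of the treatment it actually received,
so that each arm's regression sees a pseudo-population resembling the whole
cohort.  Stratified balance tables verify that limbs with similar propensity
look alike across arms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .cohort import CONTINUOUS_FEATURES, QUAD_FEATURE

__all__ = [
    "PropensityModel",
    "fit_propensity",
    "ipw_weights",
    "stratified_balance",
    "evaluate_propensity",
    "classification_rates",
    "ClassificationRates",
]

#: Default clipping bounds for estimated propensities before inversion.
DEFAULT_CLIP = (0.05, 0.95)


def _feature_columns(cohort: pd.DataFrame) -> list[str]:
    """All pre-treatment feature columns present in a cohort table."""
    known = set(CONTINUOUS_FEATURES) | {QUAD_FEATURE}
    return [c for c in cohort.columns
            if c in known or c.startswith("nuisance_")]


@dataclass
class PropensityModel:
    """Fitted probabilistic surgery-assignment classifier."""

    classifier: RandomForestClassifier
    features: list[str]
    n_trees: int
    seed: int

    def predict_proba(self, cohort: pd.DataFrame) -> np.ndarray:
        """Estimated probability of surgery for each row."""
        X = cohort[self.features].to_numpy(float)
        surgery_col = list(self.classifier.classes_).index(1)
        return self.classifier.predict_proba(X)[:, surgery_col]


def fit_propensity(cohort: pd.DataFrame,
                   features: Sequence[str] | None = None,
                   n_trees: int = 100, seed: int = 0) -> PropensityModel:
    """Fit the random-forest propensity model on a labelled cohort.

    All limbs are used, including those without follow-up: attrition does
    not affect what treatment a limb was assigned.  Class priors are
    rebalanced to 50/50 (``class_weight='balanced'``) so the arm imbalance
    of the cohort does not dominate the fit.
    """
    arms = cohort["arm"].unique()
    if len(arms) < 2:
        raise ValueError(f"cohort contains a single arm ({arms.tolist()}); "
                         "propensity cannot be estimated")
    if features is None:
        features = _feature_columns(cohort)
    features = list(features)
    X = cohort[features].to_numpy(float)
    y = (cohort["arm"] == "surgery").to_numpy().astype(int)
    clf = RandomForestClassifier(n_estimators=n_trees, class_weight="balanced",
                                 random_state=seed, n_jobs=1)
    clf.fit(X, y)
    return PropensityModel(classifier=clf, features=features,
                           n_trees=n_trees, seed=seed)


def ipw_weights(p_hat: np.ndarray, arm: Sequence[str],
                clip: tuple[float, float] = DEFAULT_CLIP,
                normalize: bool = True) -> np.ndarray:
    """Inverse-propensity weights for the treatment each limb received.

    Surgery limbs get ``1 / p_hat``, control limbs ``1 / (1 - p_hat)``, with
    ``p_hat`` clipped into ``clip`` first so weights stay finite; unlikely
    treatment decisions are thereby upweighted in their own arm's
    regression.  With ``normalize=True`` weights are rescaled to mean 1
    within each arm, which changes only the reported weighted-RSS scale,
    never the fitted coefficients.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    if np.any((p_hat < 0) | (p_hat > 1)):
        raise ValueError("propensities must lie in [0, 1]")
    lo, hi = clip
    if not 0 <= lo < hi <= 1:
        raise ValueError("invalid clipping bounds")
    p = np.clip(p_hat, lo, hi)
    is_surgery = np.asarray(arm) == "surgery"
    w = np.where(is_surgery, 1.0 / p, 1.0 / (1.0 - p))
    if normalize:
        for mask in (is_surgery, ~is_surgery):
            if mask.any():
                w[mask] /= w[mask].mean()
    return w


def stratified_balance(cohort: pd.DataFrame, p_hat: np.ndarray,
                       features: Sequence[str] | None = None,
                       n_bins: int = 5) -> pd.DataFrame:
    """Covariate balance within equal-width propensity strata.

    Returns one row per (stratum, feature) with per-arm counts, means and
    medians plus the between-arm standardized mean difference
    ``(mean_surgery - mean_control) / sqrt((var_s + var_c) / 2)``.  Bins
    cover [0, 1]; statistics for empty or single-arm strata are absent (NaN).
    """
    if features is None:
        features = _feature_columns(cohort)
    p_hat = np.asarray(p_hat, dtype=float)
    if len(p_hat) != len(cohort):
        raise ValueError("p_hat must cover every limb in the cohort")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    bin_idx = np.clip(np.digitize(p_hat, edges[1:-1]), 0, n_bins - 1)
    is_surgery = (cohort["arm"] == "surgery").to_numpy()

    rows = []
    for b in range(n_bins):
        in_bin = bin_idx == b
        label = f"[{edges[b]:.1f}, {edges[b + 1]:.1f})"
        for feat in features:
            x = cohort[feat].to_numpy(float)
            xs, xc = x[in_bin & is_surgery], x[in_bin & ~is_surgery]
            row = {"bin": label, "bin_low": edges[b], "bin_high": edges[b + 1],
                   "feature": feat, "n_surgery": len(xs), "n_control": len(xc),
                   "mean_surgery": np.nan, "mean_control": np.nan,
                   "median_surgery": np.nan, "median_control": np.nan,
                   "smd": np.nan}
            if len(xs):
                row["mean_surgery"] = xs.mean()
                row["median_surgery"] = np.median(xs)
            if len(xc):
                row["mean_control"] = xc.mean()
                row["median_control"] = np.median(xc)
            if len(xs) > 1 and len(xc) > 1:
                pooled = np.sqrt((xs.var(ddof=1) + xc.var(ddof=1)) / 2.0)
                if pooled > 0:
                    row["smd"] = (xs.mean() - xc.mean()) / pooled
                elif xs.mean() == xc.mean():
                    row["smd"] = 0.0
            rows.append(row)
    return pd.DataFrame(rows)


class ClassificationRates(NamedTuple):
    accuracy: float
    sensitivity: float
    specificity: float


def classification_rates(y_true: np.ndarray, p_hat: np.ndarray,
                         threshold: float = 0.5) -> ClassificationRates:
    """Accuracy / sensitivity / specificity of thresholded probabilities.

    Surgery (``y_true == 1``) is the positive class; limbs with
    ``p_hat >= threshold`` are called surgical.
    """
    y_true = np.asarray(y_true).astype(bool)
    pred = np.asarray(p_hat, dtype=float) >= threshold
    accuracy = float((pred == y_true).mean())
    n_pos, n_neg = int(y_true.sum()), int((~y_true).sum())
    sensitivity = float((pred & y_true).sum() / n_pos) if n_pos else np.nan
    specificity = float((~pred & ~y_true).sum() / n_neg) if n_neg else np.nan
    return ClassificationRates(accuracy, sensitivity, specificity)


def evaluate_propensity(model: PropensityModel, cohort: pd.DataFrame,
                        threshold: float = 0.5) -> ClassificationRates:
    """Classification performance of a propensity model on a labelled cohort."""
    p_hat = model.predict_proba(cohort)
    y = (cohort["arm"] == "surgery").to_numpy().astype(int)
    return classification_rates(y, p_hat, threshold)
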