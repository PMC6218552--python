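"""Per-arm sparse, propensity-weighted linear models of follow-up GDI.

Model building is two-stage.  First, an l1-regularized (lasso) path on
standardized candidate features, with weighted 10-fold cross-validation and
the one-standard-error rule, picks the sparsest feature subset whose
held-out error is statistically indistinguishable from the best; second, an
ordinary weighted least-squares refit on that subset, in natural units,
yields the reported coefficients, their covariance and the residual
variance.  Standardized effect sizes (coefficient x training SD of the
feature) make coefficients comparable across features with different units,
and per-limb predictive intervals combine coefficient and residual
uncertainty.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

__all__ = [
    "SelectionResult",
    "OutcomeModel",
    "StandardizedEffect",
    "select_features",
    "fit_weighted_ols",
    "standardized_effects",
    "predict_with_interval",
    "save_model_card",
    "load_model_card",
]


# ---------------------------------------------------------------------------
# l1 feature selection
# ---------------------------------------------------------------------------

@dataclass
class SelectionResult:
    """Outcome of the cross-validated lasso sparsity search."""

    penalties: np.ndarray          # descending grid
    cv_mean: np.ndarray            # mean weighted validation MSE per penalty
    cv_se: np.ndarray              # between-fold SE per penalty
    chosen_penalty: float
    selected_features: list[str]
    n_folds: int
    dropped_constant: list[str] = field(default_factory=list)


def _as_matrix(X, feature_names=None):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, dtype=float)
    if feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    return X, list(feature_names)


def _weighted_moments(X: np.ndarray, w: np.ndarray):
    mu = np.average(X, axis=0, weights=w)
    var = np.average((X - mu) ** 2, axis=0, weights=w)
    return mu, np.sqrt(var)


def default_penalty_grid(X_std: np.ndarray, y: np.ndarray, w: np.ndarray,
                         n_penalties: int = 100, decades: float = 4.0) -> np.ndarray:
    """Log-spaced grid from the smallest penalty zeroing every coefficient
    down ``decades`` orders of magnitude."""
    ybar = np.average(y, weights=w)
    alpha_max = np.max(np.abs((w * (y - ybar)) @ X_std)) / w.sum()
    return np.geomspace(alpha_max, alpha_max * 10.0 ** -decades, n_penalties)


def _weighted_lasso_path(X_std, y, w, alphas):
    """Coefficient path of the weighted lasso with intercept.

    The weighted problem (objective ``sum_i w_i (y_i - b0 - x_i b)^2 / (2
    sum_i w_i) + alpha ||b||_1``) is reduced to an unweighted, centered one
    by absorbing sqrt-weights into the rows after centering at the weighted
    means.
    """
    n = len(y)
    mu_x, _ = _weighted_moments(X_std, w)
    mu_y = np.average(y, weights=w)
    scale = np.sqrt(w * n / w.sum())
    Xt = (X_std - mu_x) * scale[:, None]
    yt = (y - mu_y) * scale
    _, coefs, _ = lasso_path(Xt, yt, alphas=alphas)
    intercepts = mu_y - mu_x @ coefs
    return coefs, intercepts  # shapes (p, n_alphas), (n_alphas,)


def select_features(X, y, w=None, n_folds: int = 10,
                    penalty_grid: np.ndarray | None = None,
                    n_penalties: int = 100, decades: float = 4.0,
                    seed: int = 0,
                    feature_names: Sequence[str] | None = None) -> SelectionResult:
    """Choose a sparse feature subset by weighted lasso + one-SE rule.

    Features are standardized (weighted mean/SD) for the path only.  For
    each fold the path is fitted on the training part and scored by weighted
    validation MSE; the chosen penalty is the largest one whose mean CV
    error is within one standard error of the minimum — the sparsest model
    that still performs adequately.  Returns the features with nonzero path
    coefficients at that penalty when refitted on all rows.
    """
    Xmat, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    n = len(y)
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if n < n_folds:
        raise ValueError(f"need at least n_folds={n_folds} rows, got {n}")

    mu, sd = _weighted_moments(Xmat, w)
    constant = sd <= 1e-12
    dropped = [names[j] for j in np.flatnonzero(constant)]
    if dropped:
        warnings.warn(f"excluding all-constant feature(s): {dropped}",
                      RuntimeWarning)
        keep = ~constant
        Xmat, mu, sd = Xmat[:, keep], mu[keep], sd[keep]
        names = [nm for nm, k in zip(names, keep) if k]
    X_std = (Xmat - mu) / sd

    if penalty_grid is None:
        penalty_grid = default_penalty_grid(X_std, y, w, n_penalties, decades)
    alphas = np.sort(np.asarray(penalty_grid, float))[::-1]

    folds = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_errors = np.empty((n_folds, len(alphas)))
    for k, (tr, va) in enumerate(folds.split(X_std)):
        coefs, intercepts = _weighted_lasso_path(X_std[tr], y[tr], w[tr], alphas)
        pred = X_std[va] @ coefs + intercepts  # (n_va, n_alphas)
        resid2 = (y[va, None] - pred) ** 2
        fold_errors[k] = np.average(resid2, axis=0, weights=w[va])

    cv_mean = fold_errors.mean(axis=0)
    cv_se = fold_errors.std(axis=0, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(cv_mean))
    cutoff = cv_mean[i_min] + cv_se[i_min]
    chosen_idx = int(np.flatnonzero(cv_mean <= cutoff)[0])  # largest penalty
    chosen = float(alphas[chosen_idx])

    coefs_full, _ = _weighted_lasso_path(X_std, y, w, alphas)
    selected = [names[j] for j in np.flatnonzero(coefs_full[:, chosen_idx] != 0.0)]
    return SelectionResult(penalties=alphas, cv_mean=cv_mean, cv_se=cv_se,
                           chosen_penalty=chosen, selected_features=selected,
                           n_folds=n_folds, dropped_constant=dropped)


# ---------------------------------------------------------------------------
# weighted least squares refit
# ---------------------------------------------------------------------------

@dataclass
class OutcomeModel:
    """Fitted per-arm linear model of follow-up GDI, natural units.

    ``covariance`` is over (intercept, *features*); ``feature_means`` and
    ``feature_sds`` are the (weighted) training moments used for
    standardized effect sizes.
    """

    arm: str
    features: list[str]
    coefficients: np.ndarray
    intercept: float
    covariance: np.ndarray
    residual_variance: float
    feature_means: np.ndarray
    feature_sds: np.ndarray
    n_obs: int
    robust: bool = False

    def coefficient(self, feature: str) -> float:
        return float(self.coefficients[self.features.index(feature)])

    def linear_predictor(self, features) -> np.ndarray:
        x = _design_from(features, self.features)
        return x @ np.concatenate([[self.intercept], self.coefficients])


def _design_from(features, needed: list[str]) -> np.ndarray:
    """Design row(s) (with leading 1) from a mapping/Series/DataFrame."""
    if isinstance(features, pd.DataFrame):
        missing = [f for f in needed if f not in features.columns]
        if missing:
            raise KeyError(f"missing feature(s) for prediction: {missing}")
        X = features[needed].to_numpy(float)
    else:
        if isinstance(features, pd.Series):
            features = features.to_dict()
        missing = [f for f in needed if f not in features]
        if missing:
            raise KeyError(f"missing feature(s) for prediction: {missing}")
        X = np.array([[float(features[f]) for f in needed]])
    return np.column_stack([np.ones(len(X)), X])


def _name_collinear_columns(A: np.ndarray, names: list[str]) -> list[str]:
    """Columns made redundant by earlier ones, via pivoted QR."""
    from scipy.linalg import qr as scipy_qr

    _, R, piv = scipy_qr(A, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(A.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    return [names[j] for j in sorted(piv[rank:])]


def fit_weighted_ols(X, y, w=None, arm: str = "",
                     robust: bool = False,
                     feature_names: Sequence[str] | None = None) -> OutcomeModel:
    """Weighted least-squares fit in natural units.

    Coefficients minimize ``sum_i w_i (y_i - yhat_i)^2``; the residual
    variance is the weighted RSS over ``n - p - 1`` (weights normalized to
    mean 1), and the coefficient covariance is ``sigma^2 (X' W X)^{-1}``.
    With ``robust=True`` a heteroscedasticity-robust (HC1-type sandwich)
    covariance is used instead.
    """
    Xmat, names = _as_matrix(X, feature_names)
    y = np.asarray(y, dtype=float)
    n, p = Xmat.shape
    if n <= p + 1:
        raise ValueError(f"need more rows ({n}) than parameters ({p + 1})")
    w = np.ones(n) if w is None else np.asarray(w, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    w = w / w.mean()

    A = np.column_stack([np.ones(n), Xmat])
    sw = np.sqrt(w)
    Aw, yw = A * sw[:, None], y * sw
    rank = np.linalg.matrix_rank(Aw)
    if rank < p + 1:
        bad = _name_collinear_columns(Aw, ["(intercept)"] + names)
        raise np.linalg.LinAlgError(
            f"design is rank-deficient; collinear column(s): {bad}")
    beta, *_ = np.linalg.lstsq(Aw, yw, rcond=None)

    resid = y - A @ beta
    dof = n - p - 1
    sigma2 = float(w @ resid**2 / dof)
    gram_inv = np.linalg.inv(Aw.T @ Aw)
    if robust:
        meat = (A * (w**2 * resid**2)[:, None]).T @ A
        cov = gram_inv @ meat @ gram_inv * (n / dof)
    else:
        cov = sigma2 * gram_inv
    cov = (cov + cov.T) / 2.0

    mu, sd = _weighted_moments(Xmat, w)
    return OutcomeModel(arm=arm, features=names,
                        coefficients=beta[1:], intercept=float(beta[0]),
                        covariance=cov, residual_variance=sigma2,
                        feature_means=mu, feature_sds=sd, n_obs=n,
                        robust=robust)


# ---------------------------------------------------------------------------
# effect sizes and prediction
# ---------------------------------------------------------------------------

@dataclass
class StandardizedEffect:
    """Change in predicted GDI per 1 training-SD of a feature."""

    feature: str
    effect: float
    effect_sd: float


def standardized_effects(model: OutcomeModel) -> list[StandardizedEffect]:
    """Coefficients rescaled to GDI change per 1 training-SD of each feature;
    the effect's SD scales the same way from the coefficient covariance."""
    out = []
    for j, name in enumerate(model.features):
        sd = model.feature_sds[j]
        coef_var = model.covariance[j + 1, j + 1]
        out.append(StandardizedEffect(
            feature=name,
            effect=float(model.coefficients[j] * sd),
            effect_sd=float(sd * np.sqrt(coef_var)),
        ))
    return out


def predict_with_interval(model: OutcomeModel, features,
                          level: float = 0.95):
    """Point prediction with a normal-quantile prediction interval.

    The half-width combines coefficient uncertainty (``x' Sigma x``) with
    residual scatter, so the interval covers an individual limb's follow-up
    GDI, not just its conditional mean.
    """
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    x = _design_from(features, model.features)
    point = x @ np.concatenate([[model.intercept], model.coefficients])
    var = np.einsum("ij,jk,ik->i", x, model.covariance, x) + model.residual_variance
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(var)
    lower, upper = point - half, point + half
    if len(point) == 1:
        return float(point[0]), float(lower[0]), float(upper[0])
    return point, lower, upper


# ---------------------------------------------------------------------------
# portable model cards
# ---------------------------------------------------------------------------

def save_model_card(model: OutcomeModel, path) -> None:
    """Serialize a fitted model as a flat structured-text card.

    The card carries everything needed to reproduce predictions and
    intervals elsewhere: features, natural-unit coefficients, intercept,
    covariance, residual variance, and training feature moments.
    """
    card = {
        "arm": model.arm,
        "features": model.features,
        "coefficients": model.coefficients.tolist(),
        "intercept": model.intercept,
        "covariance": model.covariance.tolist(),
        "residual_variance": model.residual_variance,
        "feature_means": model.feature_means.tolist(),
        "feature_sds": model.feature_sds.tolist(),
        "n_obs": model.n_obs,
        "robust": model.robust,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(card, fh, sort_keys=False)


def load_model_card(path) -> OutcomeModel:
    with open(path) as fh:
        card = yaml.safe_load(fh)
    return OutcomeModel(
        arm=card["arm"], features=list(card["features"]),
        coefficients=np.asarray(card["coefficients"], float),
        intercept=float(card["intercept"]),
        covariance=np.asarray(card["covariance"], float),
        residual_variance=float(card["residual_variance"]),
        feature_means=np.asarray(card["feature_means"], float),
        feature_sds=np.asarray(card["feature_sds"], float),
        n_obs=int(card["n_obs"]), robust=bool(card.get("robust", False)),
    )
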