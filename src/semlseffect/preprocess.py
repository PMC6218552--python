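"""Pre-modelling feature construction.

Three operators are applied to raw clinical gait data before any modelling:

* non-dimensionalization of spatio-temporal parameters (walking speed by
  ``sqrt(g * leg_length)``, step length by leg length) so body size does not
  leak into the models;
* mean imputation of sporadically missing values;
* condensation of noisy-but-correlated joint-level physical-exam items
  (manual muscle strength, selective motor control, spasticity) into one
  summary score per modality, via an iterative first-principal-component fit
  that re-imputes missing cells from the rank-1 reconstruction at each pass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["nondimensionalize", "mean_impute", "summary_score", "SummaryScore"]

GRAVITY = 9.81  # m/s^2


def nondimensionalize(value, kind: str, leg_length, g: float = GRAVITY):
    """Scale a spatio-temporal gait parameter into dimensionless form.

    ``kind='speed'`` divides by ``sqrt(g * leg_length)``; ``kind='step_length'``
    divides by leg length.  Accepts scalars or arrays.
    """
    leg_length = np.asarray(leg_length, dtype=float)
    if np.any(leg_length <= 0):
        raise ValueError("leg length must be strictly positive")
    value = np.asarray(value, dtype=float)
    if kind == "speed":
        out = value / np.sqrt(g * leg_length)
    elif kind == "step_length":
        out = value / leg_length
    else:
        raise ValueError(f"unknown kind {kind!r}; expected 'speed' or 'step_length'")
    return float(out) if out.ndim == 0 else out


def mean_impute(matrix) -> np.ndarray:
    """Replace missing entries with their column's observed mean.

    Observed entries are untouched, so column means are preserved exactly.
    A fully missing column cannot be imputed and raises ``ValueError``.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        names = list(matrix.columns)
    else:
        values = np.array(matrix, dtype=float)
        names = [str(j) for j in range(values.shape[1])] if values.ndim == 2 else []
    if values.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    out = values.copy()
    missing = np.isnan(out)
    fully_missing = missing.all(axis=0)
    if fully_missing.any():
        bad = [names[j] for j in np.flatnonzero(fully_missing)]
        raise ValueError(f"cannot impute fully missing column(s): {bad}")
    col_means = np.nanmean(out, axis=0)
    out[missing] = np.broadcast_to(col_means, out.shape)[missing]
    return out


@dataclass
class SummaryScore:
    """Per-limb scalar condensation of one exam modality.

    ``scores`` are standardized (mean 0, SD 1 on the fitting set) and
    sign-fixed so that higher always means more function; ``loadings`` is the
    unit-norm item weight vector on the standardized items.
    """

    scores: np.ndarray
    loadings: np.ndarray
    modality: str | None = None
    converged: bool = True
    n_iterations: int = 0


def summary_score(items, modality: str | None = None,
                  max_iterations: int = 100, tolerance: float = 1e-8,
                  negate: bool | None = None) -> SummaryScore:
    """First-principal-component summary of correlated exam items with
    robust handling of missing cells.

    The algorithm alternates: mean-impute missing cells, standardize
    columns, take the first principal component, replace the missing cells
    by their rank-1 reconstruction, and repeat until the scores move less
    than ``tolerance`` (sup-norm) or ``max_iterations`` is hit; with complete
    data it reduces to plain first-PC scores of the standardized matrix.

    The loading vector is flipped if its entries sum to a negative value, so
    that for strength/selective-motor-control items a higher score means
    more function.  Spasticity items should be negated before scoring
    (``negate=True``, the default when ``modality='spasticity'``) so the
    same convention holds: higher score, less spasticity.
    """
    if isinstance(items, pd.DataFrame):
        values = items.to_numpy(dtype=float)
    else:
        values = np.array(items, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("need a matrix with at least 2 item columns")
    n_obs = (~np.isnan(values)).sum(axis=0)
    if (n_obs < 2).any():
        raise ValueError("each item column needs at least 2 observed values")
    if negate is None:
        negate = modality == "spasticity"
    if negate:
        values = -values

    missing = np.isnan(values)
    filled = mean_impute(values)
    prev_scores = None
    converged = False
    iteration = 0
    for iteration in range(1, max_iterations + 1):
        mu = filled.mean(axis=0)
        sd = filled.std(axis=0, ddof=0)
        sd = np.where(sd > 0, sd, 1.0)
        z = (filled - mu) / sd
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        scores = u[:, 0] * s[0]
        loadings = vt[0]
        if not missing.any():
            converged = True
            break
        recon_z = np.outer(scores, loadings)
        filled[missing] = (recon_z * sd + mu)[missing]
        if prev_scores is not None:
            if np.max(np.abs(scores - prev_scores)) < tolerance:
                converged = True
                break
        prev_scores = scores
    if not converged:
        warnings.warn(
            f"summary_score did not converge in {max_iterations} iterations; "
            "returning last iterate", RuntimeWarning)

    if loadings.sum() < 0:
        loadings = -loadings
        scores = -scores
    scores = (scores - scores.mean()) / scores.std(ddof=0)
    return SummaryScore(scores=scores, loadings=loadings, modality=modality,
                        converged=converged, n_iterations=iteration)
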