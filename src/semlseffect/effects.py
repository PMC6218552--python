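"""Per-limb counterfactual effect estimation and cohort summaries.

The surgery and control outcome models jointly estimate what no single limb
can show: its follow-up GDI both with and without surgery.  The estimated
effect of surgery for a limb is the difference of the two predictions;
95% prediction intervals are reported per arm (the two models' coefficient
covariances are estimated separately, so no interval is formed for the
difference itself).  Cohort-level summaries count limbs with any positive
expected effect and with a clinically meaningful one (>= 5 GDI points by
default), and each limb is flagged by how its observed treatment compares
with its expected benefit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .regression import OutcomeModel, predict_with_interval

__all__ = [
    "EffectEstimate",
    "estimate_effect",
    "estimate_effects",
    "adequacy_flag",
    "cohort_effect_summary",
    "EffectSummary",
    "MEANINGFUL_EFFECT_GDI",
]

#: Minimal clinically meaningful improvement in GDI.
MEANINGFUL_EFFECT_GDI = 5.0

ADEQUACY_FLAGS = ("under_treated", "appropriately_treated", "over_treated",
                  "conservatively_treated", "indeterminate")


@dataclass
class EffectEstimate:
    """Estimated counterfactual outcomes and surgery effect for one limb."""

    limb_id: object
    pred_gdi_surgery: float
    pred_gdi_control: float
    effect: float
    interval_surgery: tuple[float, float]
    interval_control: tuple[float, float]
    observed_arm: str | None = None
    adequacy: str | None = None


def adequacy_flag(effect: float, observed_arm: str,
                  meaningful_threshold: float = MEANINGFUL_EFFECT_GDI) -> str:
    """Label the observed treatment decision against the expected benefit.

    Control limbs expected to gain at least the meaningful threshold were
    under-treated; other control limbs were (appropriately) conservatively
    treated.  Surgery limbs with no expected benefit (effect <= 0) were
    over-treated; those at or above the threshold were appropriately
    treated; surgery limbs in between are indeterminate.
    """
    if observed_arm == "control":
        return ("under_treated" if effect >= meaningful_threshold
                else "conservatively_treated")
    if observed_arm == "surgery":
        if effect <= 0.0:
            return "over_treated"
        if effect >= meaningful_threshold:
            return "appropriately_treated"
        return "indeterminate"
    raise ValueError(f"unknown arm {observed_arm!r}")


def estimate_effect(features, surgery_model: OutcomeModel,
                    control_model: OutcomeModel,
                    observed_arm: str | None = None,
                    limb_id=None, level: float = 0.95,
                    meaningful_threshold: float = MEANINGFUL_EFFECT_GDI) -> EffectEstimate:
    """Predict one limb's follow-up GDI under both arms and their difference."""
    ps, lo_s, hi_s = predict_with_interval(surgery_model, features, level)
    pc, lo_c, hi_c = predict_with_interval(control_model, features, level)
    effect = ps - pc
    flag = (adequacy_flag(effect, observed_arm, meaningful_threshold)
            if observed_arm is not None else None)
    return EffectEstimate(limb_id=limb_id,
                          pred_gdi_surgery=ps, pred_gdi_control=pc,
                          effect=effect,
                          interval_surgery=(lo_s, hi_s),
                          interval_control=(lo_c, hi_c),
                          observed_arm=observed_arm, adequacy=flag)


def estimate_effects(cohort: pd.DataFrame, surgery_model: OutcomeModel,
                     control_model: OutcomeModel, level: float = 0.95,
                     meaningful_threshold: float = MEANINGFUL_EFFECT_GDI) -> pd.DataFrame:
    """Vectorized per-limb effect table for a whole cohort."""
    ps, lo_s, hi_s = predict_with_interval(surgery_model, cohort, level)
    pc, lo_c, hi_c = predict_with_interval(control_model, cohort, level)
    ps, pc = np.atleast_1d(ps), np.atleast_1d(pc)
    lo_s, hi_s = np.atleast_1d(lo_s), np.atleast_1d(hi_s)
    lo_c, hi_c = np.atleast_1d(lo_c), np.atleast_1d(hi_c)
    effect = ps - pc
    out = pd.DataFrame({
        "limb_id": cohort["limb_id"].to_numpy()
        if "limb_id" in cohort else np.arange(len(cohort)),
        "pred_gdi_surgery": ps, "pred_gdi_control": pc, "effect": effect,
        "surgery_lower": lo_s, "surgery_upper": hi_s,
        "control_lower": lo_c, "control_upper": hi_c,
    })
    if "arm" in cohort:
        out["observed_arm"] = cohort["arm"].to_numpy()
        out["adequacy"] = [
            adequacy_flag(e, a, meaningful_threshold)
            for e, a in zip(effect, out["observed_arm"])
        ]
    return out


@dataclass
class EffectSummary:
    """Cohort-level distribution of estimated surgery effects."""

    n_limbs: int
    positive_fraction: float       # effect strictly > 0
    meaningful_fraction: float     # effect >= threshold
    meaningful_threshold: float
    meaningful_arm_shares: dict    # among meaningful limbs, share per arm
    histogram_counts: np.ndarray
    histogram_edges: np.ndarray


def cohort_effect_summary(estimates, meaningful_threshold: float = MEANINGFUL_EFFECT_GDI,
                          n_hist_bins: int = 30) -> EffectSummary:
    """Summarize per-limb effect estimates across a cohort.

    ``estimates`` may be the DataFrame from :func:`estimate_effects`, a list
    of :class:`EffectEstimate`, or a bare array of effects.  Positivity is
    strict (> 0); 'meaningful' means at least the threshold.
    """
    arms = None
    if isinstance(estimates, pd.DataFrame):
        effects = estimates["effect"].to_numpy(float)
        if "observed_arm" in estimates:
            arms = estimates["observed_arm"].to_numpy()
    elif len(estimates) and isinstance(estimates[0], EffectEstimate):
        effects = np.array([e.effect for e in estimates], float)
        if all(e.observed_arm is not None for e in estimates):
            arms = np.array([e.observed_arm for e in estimates])
    else:
        effects = np.asarray(estimates, dtype=float)
    if effects.size == 0:
        raise ValueError("no effect estimates to summarize")

    meaningful = effects >= meaningful_threshold
    shares = {}
    if arms is not None and meaningful.any():
        sub = arms[meaningful]
        shares = {arm: float((sub == arm).mean()) for arm in np.unique(arms)}
    counts, edges = np.histogram(effects, bins=n_hist_bins)
    return EffectSummary(
        n_limbs=len(effects),
        positive_fraction=float((effects > 0).mean()),
        meaningful_fraction=float(meaningful.mean()),
        meaningful_threshold=meaningful_threshold,
        meaningful_arm_shares=shares,
        histogram_counts=counts, histogram_edges=edges,
    )
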