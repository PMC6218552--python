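"""End-to-end harness: split, fit, evaluate, repeat, aggregate.

A cohort is split once (70/30, stratified by arm) and the whole
model-building chain — propensity fit on all training limbs, inverse-
propensity weights, per-arm lasso feature selection and weighted
least-squares refit on the follow-up subset, unweighted evaluation on the
held-out test limbs — is repeated many times (1,000 by default) varying only
the training-phase randomness (classifier seed, CV fold assignment).
Aggregation across repetitions yields per-feature inclusion frequencies, a
consensus feature set (features selected in at least 80% of repetitions),
coefficient and effect-size distributions, and test-metric distributions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .effects import MEANINGFUL_EFFECT_GDI
from .metrics import EvalReport, evaluate_predictions
from .propensity import (DEFAULT_CLIP, PropensityModel, _feature_columns,
                         evaluate_propensity, fit_propensity, ipw_weights)
from .regression import (OutcomeModel, SelectionResult, fit_weighted_ols,
                         select_features, standardized_effects)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "RepetitionSummary",
    "split_cohort",
    "run_pipeline_once",
    "repeat_and_summarize",
]

logger = logging.getLogger("semlseffect")

CONSENSUS_INCLUSION = 0.80


@dataclass
class PipelineConfig:
    """Tunable knobs of one pipeline run (defaults follow the study design)."""

    train_fraction: float = 0.7
    n_trees: int = 100
    propensity_clip: tuple[float, float] = DEFAULT_CLIP
    n_folds: int = 10
    n_penalties: int = 100
    penalty_decades: float = 4.0
    gdi_threshold: float = 80.0
    meaningful_threshold: float = MEANINGFUL_EFFECT_GDI
    robust_covariance: bool = False
    propensity_features: list[str] | None = None
    candidate_features: list[str] | None = None


@dataclass
class PipelineResult:
    """Artifacts of a single train/evaluate pass."""

    propensity_model: PropensityModel
    weights_train: np.ndarray
    selection_surgery: SelectionResult
    selection_control: SelectionResult
    model_surgery: OutcomeModel
    model_control: OutcomeModel
    eval_surgery: EvalReport
    eval_control: EvalReport
    propensity_eval_train: tuple
    propensity_eval_test: tuple


def split_cohort(cohort: pd.DataFrame, train_fraction: float = 0.7,
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Disjoint, exhaustive train/test partition, stratified by arm.

    Within each arm, ``round(train_fraction * n_arm)`` limbs go to training,
    so arm proportions in each half stay within one limb of the cohort's.
    The split is a function of (cohort, seed) only and is meant to stay
    fixed across repetitions.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for arm in sorted(cohort["arm"].unique()):
        idx = np.flatnonzero((cohort["arm"] == arm).to_numpy())
        n_train = round(train_fraction * len(idx))
        if n_train == 0 or n_train == len(idx):
            raise ValueError(
                f"arm {arm!r} cannot populate both halves "
                f"({len(idx)} limbs at fraction {train_fraction})")
        perm = rng.permutation(idx)
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = cohort.iloc[np.sort(np.concatenate(train_idx))].reset_index(drop=True)
    test = cohort.iloc[np.sort(np.concatenate(test_idx))].reset_index(drop=True)
    return train, test


def _stage(name):
    """Decorator-free stage annotation for error propagation."""
    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, _StageError):
                raise _StageError(f"[{name}] {exc}") from exc
            return False
    return _Ctx()


class _StageError(RuntimeError):
    pass


def run_pipeline_once(train: pd.DataFrame, test: pd.DataFrame,
                      config: PipelineConfig | None = None,
                      seed: int = 0) -> PipelineResult:
    """One full model-building and evaluation pass on a fixed split.

    Propensity is fitted on every training limb (follow-up attrition does
    not hide the treatment decision); the per-arm outcome models use only
    limbs with follow-up.  Evaluation is unweighted, per arm, on the test
    limbs with follow-up.  Fully deterministic given (train, test, config,
    seed).
    """
    config = config or PipelineConfig()

    with _stage("propensity"):
        prop = fit_propensity(train, features=config.propensity_features,
                              n_trees=config.n_trees, seed=seed)
        p_hat = prop.predict_proba(train)
        weights = ipw_weights(p_hat, train["arm"], clip=config.propensity_clip)
        prop_train = evaluate_propensity(prop, train)
        prop_test = evaluate_propensity(prop, test)
    logger.info("propensity: n_train=%d train_acc=%.3f test_acc=%.3f",
                len(train), prop_train.accuracy, prop_test.accuracy)

    candidates = config.candidate_features or _feature_columns(train)
    selections: dict[str, SelectionResult] = {}
    models: dict[str, OutcomeModel] = {}
    evals: dict[str, EvalReport] = {}
    for arm in ("surgery", "control"):
        mask = ((train["arm"] == arm) & train["followup_available"]).to_numpy()
        X = train.loc[mask, candidates]
        y = train.loc[mask, "gdi_followup"].to_numpy(float)
        w = weights[mask]
        with _stage(f"select:{arm}"):
            sel = select_features(X, y, w, n_folds=config.n_folds,
                                  n_penalties=config.n_penalties,
                                  decades=config.penalty_decades, seed=seed)
        with _stage(f"fit:{arm}"):
            model = fit_weighted_ols(X[sel.selected_features], y, w, arm=arm,
                                     robust=config.robust_covariance)
        with _stage(f"evaluate:{arm}"):
            test_mask = ((test["arm"] == arm)
                         & test["followup_available"]).to_numpy()
            y_test = test.loc[test_mask, "gdi_followup"].to_numpy(float)
            y_pred = model.linear_predictor(test.loc[test_mask])
            report = evaluate_predictions(y_test, y_pred, config.gdi_threshold)
        logger.info("%s: n_fit=%d n_test=%d selected=%d R2=%.3f AUC=%.3f",
                    arm, int(mask.sum()), int(test_mask.sum()),
                    len(sel.selected_features), report.r_squared, report.auc)
        selections[arm], models[arm], evals[arm] = sel, model, report

    return PipelineResult(
        propensity_model=prop, weights_train=weights,
        selection_surgery=selections["surgery"],
        selection_control=selections["control"],
        model_surgery=models["surgery"], model_control=models["control"],
        eval_surgery=evals["surgery"], eval_control=evals["control"],
        propensity_eval_train=prop_train, propensity_eval_test=prop_test,
    )


@dataclass
class RepetitionSummary:
    """Aggregates over repeated refits of the same split."""

    n_reps: int
    n_failures: int
    inclusion_frequency: dict      # arm -> {feature: proportion}
    consensus_features: dict       # arm -> [features with freq >= 0.80]
    median_model_size: dict        # arm -> median count of selected features
    coefficient_stats: dict        # arm -> {feature: (mean, sd)} where selected
    effect_stats: dict             # arm -> {feature: (mean, sd)} standardized
    metric_distributions: dict     # arm -> {metric: np.ndarray over reps}


def repeat_and_summarize(train: pd.DataFrame, test: pd.DataFrame,
                         config: PipelineConfig | None = None,
                         n_reps: int = 1000, base_seed: int = 0,
                         max_failure_fraction: float = 0.10) -> RepetitionSummary:
    """Repeat the pipeline, varying only training randomness, and aggregate.

    Repetition ``i`` uses seed ``base_seed + i`` for the classifier and the
    CV fold assignment; the split itself stays fixed.  Coefficient and
    standardized-effect statistics for a feature are computed only over the
    repetitions that selected it.  Individual failures are logged and
    skipped; more than ``max_failure_fraction`` of them aborts the run.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be at least 2")
    config = config or PipelineConfig()
    arms = ("surgery", "control")
    inclusions = {a: [] for a in arms}
    coefs = {a: [] for a in arms}
    effects = {a: [] for a in arms}
    metrics = {a: {"r_squared": [], "accuracy": [], "auc": []} for a in arms}
    sizes = {a: [] for a in arms}
    n_failures = 0

    for i in range(n_reps):
        try:
            result = run_pipeline_once(train, test, config, seed=base_seed + i)
        except Exception as exc:  # noqa: BLE001 - any stage failure is skipped
            n_failures += 1
            logger.warning("repetition %d failed: %s", i, exc)
            if n_failures > max_failure_fraction * n_reps:
                raise RuntimeError(
                    f"{n_failures} of {i + 1} repetitions failed "
                    f"(> {max_failure_fraction:.0%}); aborting") from exc
            continue
        for arm, model, report in (
            ("surgery", result.model_surgery, result.eval_surgery),
            ("control", result.model_control, result.eval_control),
        ):
            inclusions[arm].append(set(model.features))
            sizes[arm].append(len(model.features))
            coefs[arm].append(dict(zip(model.features, model.coefficients)))
            effects[arm].append({e.feature: e.effect
                                 for e in standardized_effects(model)})
            metrics[arm]["r_squared"].append(report.r_squared)
            metrics[arm]["accuracy"].append(report.accuracy)
            metrics[arm]["auc"].append(report.auc)

    n_done = n_reps - n_failures
    inclusion_freq, consensus, coef_stats, eff_stats, med_size = {}, {}, {}, {}, {}
    for arm in arms:
        all_feats = sorted(set().union(*inclusions[arm]) if inclusions[arm] else set())
        freq = {f: sum(f in s for s in inclusions[arm]) / n_done
                for f in all_feats}
        inclusion_freq[arm] = freq
        consensus[arm] = [f for f, p in freq.items() if p >= CONSENSUS_INCLUSION]
        med_size[arm] = float(np.median(sizes[arm]))
        coef_stats[arm] = {
            f: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for f in all_feats
            if (v := [c[f] for c in coefs[arm] if f in c])
        }
        eff_stats[arm] = {
            f: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
            for f in all_feats
            if (v := [e[f] for e in effects[arm] if f in e])
        }

    return RepetitionSummary(
        n_reps=n_done, n_failures=n_failures,
        inclusion_frequency=inclusion_freq, consensus_features=consensus,
        median_model_size=med_size, coefficient_stats=coef_stats,
        effect_stats=eff_stats,
        metric_distributions={
            a: {m: np.asarray(v) for m, v in metrics[a].items()} for a in arms
        },
    )
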