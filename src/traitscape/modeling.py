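"""Boosted-tree trait-environment models under leave-one-fold-out CV.

One model task is a (trait, resolution, data subset) triple.  The subset
decides which label sources enter training — survey cells only (SCI),
occurrence cells only (CIT), or the survey-precedence merge (COMB) — but
validation is always against survey-sourced community-weighted means from
the held-out spatial fold, so the three subsets are scored on a common
footing.  The learner is a gradient-boosted regression tree ensemble
(LightGBM backend) that tolerates missing predictor values natively by
routing them to the loss-minimising side of each split.

Occurrence rows in the merged subset are down-weighted inversely to their
proportion so that surveys and occurrences contribute equal total weight.
Features can be pruned per split by backward elimination on permutation
importance measured on an internal tune set held out of the split's
training rows.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor

from .gridding import SOURCE_OCCURRENCE, SOURCE_SURVEY

logger = logging.getLogger(__name__)

__all__ = [
    "ModelConfig",
    "CVResult",
    "compute_weights",
    "fit_trait_model",
    "predict_with_model",
    "permutation_importance",
    "prune_features",
    "cv_run",
    "plan_model_tasks",
]

SUBSETS = ("SCI", "CIT", "COMB")

#: Learner defaults: a few hundred shallow trees, sized for tables of
#: 10^2-10^4 rows.  ``min_child_samples`` is small because labelled cells
#: are scarce compared to typical LightGBM workloads.
DEFAULT_LEARNER_PARAMS: dict = {
    "n_estimators": 300,
    "learning_rate": 0.06,
    "num_leaves": 31,
    "min_child_samples": 5,
    "subsample": 1.0,
    "colsample_bytree": 1.0,
}


@dataclass
class ModelConfig:
    """Configuration for one (trait, resolution, subset) model task."""

    trait: str = "trait"
    resolution_km: float = 1.0
    subset: str = "COMB"
    learner_params: dict = field(default_factory=dict)
    prune: bool = False
    prune_max_iter: int = 5
    prune_criterion: str = "importance"  # or "metric_gain"
    prune_tolerance: float = 0.05  # guarded-improvement band on tune loss
    #: a feature is dropped when its importance <= this many null standard
    #: deviations of the permutation draw (0 reproduces a hard <= 0 cut;
    #: the default treats "not significantly positive" as prunable, since
    #: a pure-noise feature's expected importance is exactly 0)
    prune_se_factor: float = 2.0
    tune_fraction: float = 0.2
    n_permutation_repeats: int = 5
    min_rows: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.subset not in SUBSETS:
            raise ValueError(f"subset must be one of {SUBSETS}, got {self.subset!r}")
        if self.prune_criterion not in ("importance", "metric_gain"):
            raise ValueError(f"unknown prune criterion {self.prune_criterion!r}")

    def resolved_learner_params(self) -> dict:
        return {**DEFAULT_LEARNER_PARAMS, **self.learner_params}


def compute_weights(source: np.ndarray, subset: str = "COMB") -> np.ndarray:
    """Per-row sample weights balancing survey against occurrence rows.

    Survey rows carry unit weight; occurrence rows are weighted by
    ``n_survey / n_occurrence`` so each source contributes the same total
    weight.  Single-source subsets (or tables) get unit weights.
    """
    source = np.asarray(source)
    w = np.ones(len(source), dtype=float)
    if subset != "COMB":
        return w
    n_survey = int((source == SOURCE_SURVEY).sum())
    n_occ = int((source == SOURCE_OCCURRENCE).sum())
    if n_survey and n_occ:
        w[source == SOURCE_OCCURRENCE] = n_survey / n_occ
    return w


def _make_learner(config: ModelConfig) -> LGBMRegressor:
    return LGBMRegressor(
        random_state=config.seed,
        deterministic=True,
        force_row_wise=True,
        n_jobs=1,
        verbose=-1,
        **config.resolved_learner_params(),
    )


def fit_trait_model(
    X: pd.DataFrame,
    y: np.ndarray,
    weights: np.ndarray | None,
    config: ModelConfig,
    features: list[str] | None = None,
) -> tuple[LGBMRegressor, list[str]]:
    """Fit the boosted-tree learner on (possibly incomplete) predictors.

    All-missing features are dropped with a warning before fitting.
    Returns the fitted learner and the feature list it was trained on
    (in order).  Deterministic under a fixed config seed and row order.
    """
    if features is None:
        features = list(X.columns)
    if len(X) < config.min_rows:
        raise ValueError(f"{len(X)} training rows < configured minimum {config.min_rows}")
    usable = [f for f in features if np.isfinite(X[f].to_numpy(dtype=float)).any()]
    dropped = set(features) - set(usable)
    if dropped:
        logger.warning("dropping all-missing features: %s", sorted(dropped))
    if not usable:
        raise ValueError("no feature has any observed value")
    model = _make_learner(config)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(X[usable], np.asarray(y, dtype=float), sample_weight=weights)
    return model, usable


def predict_with_model(model: LGBMRegressor, X: pd.DataFrame) -> np.ndarray:
    """Predict with the model's own feature list (extra columns ignored)."""
    feats = list(model.feature_name_)
    return model.predict(X[feats])


def permutation_importance(
    model: LGBMRegressor,
    X: pd.DataFrame,
    y: np.ndarray,
    features_or_groups: list[str] | dict[str, list[str]] | None = None,
    n_repeats: int = 5,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean loss increase when a feature (or feature group) is shuffled.

    Loss is squared error on the (transformed) label scale, evaluated on
    rows held out of training.  A group's columns are shuffled jointly
    with one shared row permutation, preserving within-group structure.
    Features the model never splits on score exactly zero.

    Returns a DataFrame indexed by feature/group name with columns
    ``importance`` (mean over repeats) and ``importance_sd``.
    """
    y = np.asarray(y, dtype=float)
    model_feats = list(model.feature_name_)
    if features_or_groups is None:
        groups = {f: [f] for f in model_feats}
    elif isinstance(features_or_groups, dict):
        groups = {k: list(v) for k, v in features_or_groups.items()}
    else:
        groups = {f: [f] for f in features_or_groups}
    for name, cols in groups.items():
        unknown = [c for c in cols if c not in X.columns]
        if unknown:
            raise KeyError(f"unknown feature(s) in group {name!r}: {unknown}")

    rng = np.random.default_rng(seed)
    base_loss = float(np.mean((predict_with_model(model, X) - y) ** 2))
    rows = np.arange(len(X))
    out = {}
    for name, cols in groups.items():
        active = [c for c in cols if c in model_feats]
        if not active:
            out[name] = (0.0, 0.0)  # never used by the model
            continue
        losses = np.empty(n_repeats)
        for rep in range(n_repeats):
            perm = rng.permutation(rows)
            Xs = X.copy()
            for c in active:
                Xs[c] = X[c].to_numpy()[perm]
            losses[rep] = np.mean((predict_with_model(model, Xs) - y) ** 2)
        delta = losses - base_loss
        out[name] = (float(delta.mean()), float(delta.std()))
    df = pd.DataFrame(
        {"importance": {k: v[0] for k, v in out.items()},
         "importance_sd": {k: v[1] for k, v in out.items()}}
    )
    df.index.name = "feature"
    return df


def prune_features(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    w_train: np.ndarray | None,
    X_tune: pd.DataFrame,
    y_tune: np.ndarray,
    config: ModelConfig,
) -> list[str]:
    """Backward feature elimination guided by tune-set importance.

    Iteratively fits the learner, measures permutation importance on the
    tune rows, and removes every feature whose importance is not
    significantly positive (shuffling it does not demonstrably hurt, so
    it carries no validated signal); stops
    when no feature qualifies or after ``prune_max_iter`` rounds.  Under
    ``prune_criterion="metric_gain"`` a candidate removal is instead
    accepted only if the refitted model's tune loss does not increase.
    If the pruned model ends up worse than the unpruned one by more than
    ``prune_tolerance`` (relative), the full feature set is restored.
    Pruning to zero features keeps the single most important one.
    """
    features = list(X_train.columns)
    if config.prune_max_iter == 0:
        return features

    def tune_loss(feats: list[str]) -> float:
        m, used = fit_trait_model(X_train, y_train, w_train, config, feats)
        pred = predict_with_model(m, X_tune)
        return float(np.mean((pred - np.asarray(y_tune, dtype=float)) ** 2))

    model, features = fit_trait_model(X_train, y_train, w_train, config, features)
    initial_loss = float(
        np.mean((predict_with_model(model, X_tune) - np.asarray(y_tune, dtype=float)) ** 2)
    )

    for it in range(config.prune_max_iter):
        imp = permutation_importance(
            model, X_tune, y_tune, features, config.n_permutation_repeats,
            seed=config.seed + it,
        )
        if config.prune_criterion == "importance":
            # null scale of the importance: the intact loss is a single draw
            # from the same distribution as the shuffled losses, so its
            # variance (~ the repeat spread) dominates, not the repeat SE
            n_rep = max(config.n_permutation_repeats, 1)
            null_sd = imp["importance_sd"] * np.sqrt(1.0 + 1.0 / n_rep)
            drop = [
                f for f in features
                if imp.loc[f, "importance"] <= config.prune_se_factor * null_sd[f]
            ]
        else:  # metric_gain: try removing the least important feature
            worst = imp["importance"].idxmin()
            drop = [worst] if tune_loss([f for f in features if f != worst]) <= tune_loss(features) else []
        if not drop:
            break
        if len(drop) >= len(features):
            keep = imp["importance"].idxmax()
            logger.warning("pruning removed every feature; keeping best (%s)", keep)
            features = [keep]
            break
        features = [f for f in features if f not in drop]
        model, features = fit_trait_model(X_train, y_train, w_train, config, features)

    final_loss = float(
        np.mean((predict_with_model(model, X_tune) - np.asarray(y_tune, dtype=float)) ** 2)
    )
    if final_loss > initial_loss * (1.0 + config.prune_tolerance):
        logger.warning(
            "pruned model tune loss %.4g exceeds unpruned %.4g beyond tolerance; "
            "restoring full feature set",
            final_loss,
            initial_loss,
        )
        return list(X_train.columns)
    return features


@dataclass
class CVResult:
    """Everything a leave-one-fold-out run produces for one model task."""

    config: ModelConfig
    split_models: list[LGBMRegressor]
    split_features: list[list[str]]
    split_folds: list[int]
    skipped_folds: list[int]
    observed: np.ndarray  # pooled validation labels (transformed scale)
    predicted: np.ndarray  # pooled validation predictions (transformed scale)
    val_strata: np.ndarray
    final_model: LGBMRegressor
    final_features: list[str]
    importance: pd.DataFrame | None = None
    split_sizes: list[int] = field(default_factory=list)  # validation pairs per split

    @property
    def n_validation_pairs(self) -> int:
        return len(self.observed)


def cv_run(
    table: pd.DataFrame,
    fold: np.ndarray,
    config: ModelConfig,
    feature_names: list[str],
    val_table: pd.DataFrame | None = None,
    val_fold: np.ndarray | None = None,
    importance_groups: dict[str, list[str]] | None = None,
) -> CVResult:
    """Leave-one-fold-out training, validation, and a final all-data model.

    ``table`` supplies the training rows of this subset; validation rows
    come from ``val_table`` (defaulting to ``table``) restricted to
    survey-sourced rows of the held-out fold — occurrence cells never
    validate.  For each split, features are optionally pruned on an
    internal tune subsample before the split model is fitted; the final
    model is fitted on all rows.  Permutation importances are averaged
    over the splits' validation rows.
    """
    from .spatial_cv import loo_splits

    fold = np.asarray(fold)
    if val_table is None:
        val_table, val_fold = table, fold
    if val_fold is None:
        raise ValueError("val_fold is required when val_table is given")
    val_fold = np.asarray(val_fold)

    rng = np.random.default_rng(config.seed)
    y = table["label"].to_numpy(dtype=float)
    X = table[feature_names]
    weights = compute_weights(table["source"].to_numpy(), config.subset)

    # validation split bookkeeping happens on the validation table
    val_splits = {
        k: np.flatnonzero((val_fold == k) & (val_table["source"].to_numpy() == SOURCE_SURVEY))
        for k in sorted(set(val_fold[val_fold > 0]))
    }

    split_models, split_features, split_folds, skipped = [], [], [], []
    obs_parts, pred_parts, strata_parts = [], [], []
    for k, val_idx in val_splits.items():
        train_idx = np.flatnonzero(fold != k)
        if len(val_idx) == 0:
            skipped.append(int(k))
            logger.warning("fold %d holds no survey validation rows; skipped", k)
            continue
        if len(train_idx) < config.min_rows:
            skipped.append(int(k))
            logger.warning("fold %d leaves too few training rows; skipped", k)
            continue

        feats = feature_names
        Xk, yk, wk = X.iloc[train_idx], y[train_idx], weights[train_idx]
        if config.prune and config.prune_max_iter > 0:
            n_tune = max(int(round(config.tune_fraction * len(train_idx))), 5)
            tune_pos = rng.choice(len(train_idx), size=min(n_tune, len(train_idx) // 2), replace=False)
            tune_mask = np.zeros(len(train_idx), dtype=bool)
            tune_mask[tune_pos] = True
            feats = prune_features(
                Xk[~tune_mask], yk[~tune_mask],
                wk[~tune_mask] if wk is not None else None,
                Xk[tune_mask], yk[tune_mask], config,
            )
        model, used = fit_trait_model(Xk, yk, wk, config, feats)
        split_models.append(model)
        split_features.append(used)
        split_folds.append(int(k))

        Xv = val_table.iloc[val_idx]
        pred_parts.append(predict_with_model(model, Xv))
        obs_parts.append(val_table["label"].to_numpy(dtype=float)[val_idx])
        strata_parts.append(
            val_table["stratum"].to_numpy()[val_idx]
            if "stratum" in val_table
            else np.zeros(len(val_idx), dtype=int)
        )

    if not split_models:
        raise RuntimeError("every fold was skipped; no cross-validation possible")

    final_model, final_features = fit_trait_model(X, y, weights, config, feature_names)

    # fold-averaged permutation importance on held-out rows
    imp_frames = []
    for model, k in zip(split_models, split_folds):
        val_idx = val_splits[k]
        if len(val_idx) < 5:
            continue
        Xv = val_table.iloc[val_idx]
        yv = val_table["label"].to_numpy(dtype=float)[val_idx]
        imp_frames.append(
            permutation_importance(
                # a shared feature list keeps the frames index-aligned even
                # when per-split pruning diverged
                model, Xv, yv, importance_groups or list(feature_names),
                config.n_permutation_repeats,
                seed=config.seed + 1000 + k,
            )
        )
    importance = None
    if imp_frames:
        importance = sum(f for f in imp_frames) / len(imp_frames)

    return CVResult(
        config=config,
        split_models=split_models,
        split_features=split_features,
        split_folds=split_folds,
        skipped_folds=skipped,
        observed=np.concatenate(obs_parts),
        predicted=np.concatenate(pred_parts),
        val_strata=np.concatenate(strata_parts),
        split_sizes=[len(p) for p in pred_parts],
        final_model=final_model,
        final_features=final_features,
        importance=importance,
    )


def plan_model_tasks(
    traits: list[str], resolutions_km: list[float], subsets: list[str] = list(SUBSETS)
) -> list[ModelConfig]:
    """Enumerate one model task per (trait, resolution, subset)."""
    for s in subsets:
        if s not in SUBSETS:
            raise ValueError(f"unknown subset {s!r}")
    return [
        ModelConfig(trait=t, resolution_km=r, subset=s)
        for t in traits
        for r in resolutions_km
        for s in subsets
    ]
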