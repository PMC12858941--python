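"""Prediction uncertainty: ensemble spread and area of applicability.

Two complementary per-pixel uncertainty layers accompany every trait map:

* **COV** — the coefficient of variation of the K cross-validation fold
  models' predictions (sd / mean, computed on the back-transformed trait
  scale), measuring how sensitive a pixel's prediction is to which part
  of the world the model saw;
* **DI / AOA** — the dissimilarity index of area-of-applicability
  analysis: a pixel's nearest-neighbour distance to the
  training data in standardised predictor space, divided by the mean
  cross-fold nearest-neighbour distance within the training data.  Pixels
  with DI above Q75 + 1.5 IQR of the training DI distribution fall
  outside the area of applicability and their predictions are flagged
  unreliable.

Missing predictor values are imputed (training-fitted median by default,
or per-feature boosted-tree regressors) before any distance is computed,
so the DI surface matches the geographic extent of the predictions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

__all__ = [
    "UncertaintyProduct",
    "cov_map",
    "impute_missing",
    "Imputer",
    "compute_di",
    "aoa_threshold",
    "aoa_coverage",
    "uncertainty_product",
]


@dataclass
class UncertaintyProduct:
    """Per-pixel uncertainty layers for one trait map."""

    cov: np.ndarray
    di: np.ndarray
    aoa: np.ndarray  # boolean, True = inside the area of applicability
    di_threshold: float
    mean_train_distance: float
    percent_inside: float


def cov_map(prediction_stack: np.ndarray, eps_frac: float = 1e-6) -> np.ndarray:
    """Pixel-wise coefficient of variation over a stack of K predictions.

    ``prediction_stack`` has shape ``(K, ...)`` with K >= 2, on the
    back-transformed (original trait units) scale.  COV = sample sd
    (denominator K-1) / mean.  Pixels whose |mean| falls below
    ``eps_frac`` times the global mean magnitude are masked NaN — the
    ratio is not meaningful around a zero mean.
    """
    stack = np.asarray(prediction_stack, dtype=float)
    if stack.ndim < 2 or stack.shape[0] < 2:
        raise ValueError("need a stack of at least two aligned prediction rasters")
    mean = np.nanmean(stack, axis=0)
    sd = np.nanstd(stack, axis=0, ddof=1)
    eps = eps_frac * max(float(np.nanmean(np.abs(mean))), np.finfo(float).tiny)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(mean) > eps, sd / np.abs(mean), np.nan)
    return out


class Imputer:
    """Training-fitted missing-value imputation, applied to new data.

    ``strategy="median"`` fills each feature with its training median;
    ``strategy="model"`` fits one boosted-tree regressor per feature on
    the remaining (median-completed) features, echoing imputers built on
    gradient-boosting backends.  Fitting uses training rows only.
    """

    def __init__(self, strategy: str = "median", seed: int = 0):
        if strategy not in ("median", "model"):
            raise ValueError(f"unknown imputation strategy {strategy!r}")
        self.strategy = strategy
        self.seed = seed
        self.medians_: pd.Series | None = None
        self.models_: dict = {}

    def fit(self, train: pd.DataFrame) -> "Imputer":
        na_all = train.columns[train.isna().all()]
        if len(na_all):
            raise ValueError(f"feature(s) with no observed value: {list(na_all)}")
        self.medians_ = train.median()
        if self.strategy == "model":
            from lightgbm import LGBMRegressor

            base = train.fillna(self.medians_)
            for col in train.columns:
                miss = train[col].isna()
                if not miss.any():
                    continue
                others = [c for c in train.columns if c != col]
                reg = LGBMRegressor(
                    n_estimators=100, num_leaves=15, min_child_samples=5,
                    random_state=self.seed, deterministic=True, n_jobs=1, verbose=-1,
                )
                reg.fit(base.loc[~miss, others], train.loc[~miss, col])
                self.models_[col] = (reg, others)
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        if self.medians_ is None:
            raise RuntimeError("imputer is not fitted")
        out = X.fillna(self.medians_)
        for col, (reg, others) in self.models_.items():
            miss = X[col].isna()
            if miss.any():
                out.loc[miss, col] = reg.predict(out.loc[miss, others])
        assert not out.isna().any().any()
        return out


def impute_missing(
    train: pd.DataFrame,
    new: pd.DataFrame | None = None,
    strategy: str = "median",
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Impute missing predictor values; fit on train, apply to both."""
    imp = Imputer(strategy=strategy, seed=seed).fit(train)
    train_c = imp.transform(train)
    new_c = imp.transform(new) if new is not None else None
    return train_c, new_c


def compute_di(
    train_features: np.ndarray,
    fold_of_train_row: np.ndarray,
    new_features: np.ndarray | None = None,
    feature_weights: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None, float]:
    """Dissimilarity index of training rows and (optionally) new points.

    Features must be complete (impute first); they are z-scored by the
    training mean/sd internally, so the DI is invariant to affine
    rescaling of any raw feature.  For each training row the distance to
    its nearest neighbour in *other* folds is computed; their mean is the
    normaliser d-bar.  A new point's DI is its nearest-neighbour distance
    to any training row divided by d-bar.

    ``feature_weights`` (e.g. permutation importances) optionally scale
    the standardized axes so distances emphasise the predictors the model
    actually relies on; the default is unweighted.

    Returns ``(train_di, new_di, mean_train_distance)``.
    """
    X = np.asarray(train_features, dtype=float)
    folds = np.asarray(fold_of_train_row)
    if X.ndim != 2:
        raise ValueError("train_features must be 2-D")
    if not np.all(np.isfinite(X)):
        raise ValueError("train features contain missing values; impute first")
    if len(np.unique(folds)) < 2:
        raise ValueError("cross-fold distances need at least two folds")

    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    w = None
    if feature_weights is not None:
        w = np.asarray(feature_weights, dtype=float)
        if w.shape != (X.shape[1],) or np.any(w < 0) or not np.any(w > 0):
            raise ValueError("feature_weights must be non-negative, one per feature")
        Z = Z * w

    # nearest neighbour in any *other* fold, per training row
    d_cross = np.empty(len(Z))
    for k in np.unique(folds):
        inside = folds == k
        tree = cKDTree(Z[~inside])
        d_cross[inside], _ = tree.query(Z[inside], k=1)
    d_bar = float(d_cross.mean())
    if d_bar <= 0:
        raise ValueError("degenerate training geometry: zero mean cross-fold distance")
    train_di = d_cross / d_bar

    new_di = None
    if new_features is not None:
        N = np.asarray(new_features, dtype=float)
        if not np.all(np.isfinite(N)):
            raise ValueError("new features contain missing values; impute first")
        Zn = (N - mu) / sd
        if w is not None:
            Zn = Zn * w
        tree = cKDTree(Z)
        d_new, _ = tree.query(Zn, k=1)
        new_di = d_new / d_bar
    return train_di, new_di, d_bar


def aoa_threshold(train_di: np.ndarray) -> float:
    """The outlier cut Q75 + 1.5 IQR of the training DI distribution.

    Quantiles use linear interpolation.  DI values at or below the
    threshold are inside the area of applicability.
    """
    di = np.asarray(train_di, dtype=float)
    if di.size < 4:
        raise ValueError("need at least four training DI values")
    q25, q75 = np.quantile(di, [0.25, 0.75])  # linear interpolation default
    return float(q75 + 1.5 * (q75 - q25))


def aoa_coverage(aoa_mask: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Percentage of valid prediction pixels inside the AOA."""
    mask = np.asarray(aoa_mask, dtype=bool)
    if valid is None:
        valid = np.ones_like(mask, dtype=bool)
    valid = np.asarray(valid, dtype=bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("no valid prediction pixels")
    return 100.0 * int((mask & valid).sum()) / n_valid


def uncertainty_product(
    prediction_stack: np.ndarray,
    train_features: pd.DataFrame,
    fold_of_train_row: np.ndarray,
    new_features: pd.DataFrame,
    valid: np.ndarray | None = None,
    impute_strategy: str = "median",
    seed: int = 0,
) -> UncertaintyProduct:
    """Assemble COV, DI, AOA and coverage for one trait map.

    ``prediction_stack`` is the (K, n_pixels) back-transformed fold
    prediction stack aligned with ``new_features`` rows; ``valid`` marks
    pixels that actually carry a prediction.
    """
    train_c, new_c = impute_missing(
        train_features, new_features, strategy=impute_strategy, seed=seed
    )
    train_di, new_di, d_bar = compute_di(
        train_c.to_numpy(), fold_of_train_row, new_c.to_numpy()
    )
    thr = aoa_threshold(train_di)
    cov = cov_map(prediction_stack)
    if valid is None:
        valid = np.isfinite(np.asarray(prediction_stack)).all(axis=0)
    aoa = (new_di <= thr) & valid
    return UncertaintyProduct(
        cov=cov,
        di=new_di,
        aoa=aoa,
        di_threshold=thr,
        mean_train_distance=d_bar,
        percent_inside=aoa_coverage(aoa, valid),
    )
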