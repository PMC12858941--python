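"""Model / Results facade over the trait-mapping machinery.

`TraitMappingModel` is constructed from a training table (labelled grid
cells joined with predictors) the way a statsmodels model is constructed
from endog/exog; ``fit()`` runs the leave-one-fold-out spatial
cross-validation and returns a :class:`TraitMappingResults` carrying the
pooled validation scores, the fold models, feature importances and the
final all-data model, with map prediction and uncertainty products as
methods of the results object.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evaluation import MetricsReport, compute_metrics
from .gridding import SOURCE_SURVEY, TraitGrid, TransformParams, invert_transform
from .grids import EnvironmentStack
from .modeling import CVResult, ModelConfig, cv_run, predict_with_model
from .spatial_cv import (
    FoldAssignment,
    assign_rows_to_folds,
    build_folds,
    empirical_variogram,
    fit_spherical,
)
from .uncertainty import UncertaintyProduct, uncertainty_product

__all__ = ["TraitMappingModel", "TraitMappingResults"]


class TraitMappingModel:
    """A trait-environment model for one (trait, resolution, subset) task.

    Parameters
    ----------
    table : training table from :func:`traitscape.gridding.build_training_table`
        (labelled cells of the subset's trait grid joined with predictors).
    feature_names : predictor column names used as model features.
    transform_params : the fitted label transform (needed to express map
        predictions in original trait units).
    config : learner / pruning / seeding configuration.
    folds : precomputed spatial fold assignment; when omitted, ``fit``
        estimates the survey CWM autocorrelation range by spherical
        semivariogram and builds KS-balanced hexagon folds itself.
    val_table : table supplying validation rows when the training table
        carries no survey cells (the occurrence-only subset); defaults to
        ``table``.
    """

    def __init__(
        self,
        table: pd.DataFrame,
        feature_names: list[str],
        transform_params: TransformParams,
        config: ModelConfig | None = None,
        folds: FoldAssignment | None = None,
        val_table: pd.DataFrame | None = None,
    ):
        self.table = table.reset_index(drop=True)
        self.feature_names = list(feature_names)
        self.transform_params = transform_params
        self.config = config or ModelConfig()
        self.folds = folds
        self.val_table = val_table.reset_index(drop=True) if val_table is not None else None

    @classmethod
    def from_grids(
        cls,
        label_grid: TraitGrid,
        env: EnvironmentStack,
        transform_params: TransformParams,
        config: ModelConfig | None = None,
        **kwargs,
    ) -> "TraitMappingModel":
        """Build the model straight from a labelled grid and predictors."""
        from .gridding import build_training_table

        table = build_training_table(label_grid, env, transform_params)
        return cls(table, env.layer_names, transform_params, config, **kwargs)

    # -- fitting -----------------------------------------------------------

    def _auto_folds(self) -> FoldAssignment:
        """Range estimation and fold construction from the data at hand."""
        val = self.val_table if self.val_table is not None else self.table
        survey = val[val["source"] == SOURCE_SURVEY]
        if len(survey) < 10:
            raise RuntimeError("too few survey rows to estimate an autocorrelation range")
        pts = survey[["x", "y"]].to_numpy()
        vg = empirical_variogram(pts, survey["label"].to_numpy(), seed=self.config.seed)
        sph = fit_spherical(vg)
        all_pts = pd.concat([self.table, val]).drop_duplicates("cell_id")
        return build_folds(
            all_pts[["x", "y"]].to_numpy(),
            all_pts["label"].to_numpy(),
            range_km=sph.range_km,
            seed=self.config.seed,
        )

    def fit(self) -> "TraitMappingResults":
        """Run the leave-one-fold-out CV and fit the final model."""
        folds = self.folds or self._auto_folds()
        fold_vec = assign_rows_to_folds(self.table[["x", "y"]].to_numpy(), folds)
        val_table = self.val_table
        val_fold = None
        if val_table is not None:
            val_fold = assign_rows_to_folds(val_table[["x", "y"]].to_numpy(), folds)
        cv = cv_run(
            self.table,
            fold_vec,
            self.config,
            self.feature_names,
            val_table=val_table,
            val_fold=val_fold,
        )
        metrics = compute_metrics(
            cv.observed,
            cv.predicted,
            strata=cv.val_strata,
            trait=self.config.trait,
            resolution_km=self.config.resolution_km,
            subset=self.config.subset,
            split_sizes=cv.split_sizes,
        )
        return TraitMappingResults(model=self, folds=folds, fold_vec=fold_vec, cv=cv, metrics=metrics)


@dataclass
class TraitMappingResults:
    """Fitted estimates, diagnostics and map products."""

    model: TraitMappingModel
    folds: FoldAssignment
    fold_vec: np.ndarray
    cv: CVResult
    metrics: MetricsReport

    # -- map products ------------------------------------------------------

    def _env_features(self, env: EnvironmentStack) -> tuple[pd.DataFrame, np.ndarray]:
        X = pd.DataFrame(env.to_table(), columns=env.layer_names)
        valid = env.valid_fraction().ravel() > 0
        return X, valid

    def predict_map(self, env: EnvironmentStack, back_transform: bool = True) -> np.ndarray:
        """Final-model trait map over the predictor stack (NaN where no predictor)."""
        X, valid = self._env_features(env)
        out = np.full(len(X), np.nan)
        out[valid] = predict_with_model(self.cv.final_model, X[valid])
        if back_transform:
            out[valid] = invert_transform(out[valid], self.model.transform_params)
        return out.reshape(env.grid.shape)

    def prediction_stack(self, env: EnvironmentStack, back_transform: bool = True) -> np.ndarray:
        """Per-fold-model prediction maps, shape (K, n_rows, n_cols)."""
        X, valid = self._env_features(env)
        maps = []
        for m in self.cv.split_models:
            out = np.full(len(X), np.nan)
            out[valid] = m.predict(X[list(m.feature_name_)][valid])
            if back_transform:
                out[valid] = invert_transform(out[valid], self.model.transform_params)
            maps.append(out.reshape(env.grid.shape))
        return np.stack(maps)

    def uncertainty(self, env: EnvironmentStack, impute_strategy: str = "median") -> UncertaintyProduct:
        """COV / DI / AOA layers for this task's map over ``env``."""
        X, valid = self._env_features(env)
        stack = self.prediction_stack(env).reshape(len(self.cv.split_models), -1)
        used = self.fold_vec > 0
        up = uncertainty_product(
            stack[:, valid],
            self.model.table.loc[used, self.model.feature_names],
            self.fold_vec[used],
            X[valid],
            impute_strategy=impute_strategy,
            seed=self.model.config.seed,
        )
        shape = env.grid.shape

        def unravel(vec, fill):
            full = np.full(np.prod(shape), fill, dtype=vec.dtype if vec.dtype != bool else bool)
            full[valid] = vec
            return full.reshape(shape)

        return UncertaintyProduct(
            cov=unravel(up.cov, np.nan),
            di=unravel(up.di, np.nan),
            aoa=unravel(up.aoa, False),
            di_threshold=up.di_threshold,
            mean_train_distance=up.mean_train_distance,
            percent_inside=up.percent_inside,
        )

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        """Persist the fitted models (LightGBM text format) plus a JSON
        sidecar with features, transform, fold provenance and scores."""
        import json
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cv.final_model.booster_.save_model(directory / "model_final.txt")
        for m, k in zip(self.cv.split_models, self.cv.split_folds):
            m.booster_.save_model(directory / f"model_fold{k}.txt")
        sidecar = {
            "config": {
                "trait": self.model.config.trait,
                "resolution_km": self.model.config.resolution_km,
                "subset": self.model.config.subset,
                "seed": self.model.config.seed,
            },
            "features": self.model.feature_names,
            "final_features": self.cv.final_features,
            "split_features": self.cv.split_features,
            "split_folds": self.cv.split_folds,
            "skipped_folds": self.cv.skipped_folds,
            "transform": self.model.transform_params.to_dict(),
            "fold_range_km": self.folds.range_km,
            "fold_balance_score": self.folds.balance_score,
            "metrics": self.metrics.to_dict(),
        }
        (directory / "model_meta.json").write_text(json.dumps(sidecar, indent=2, default=float))

    # -- reporting ---------------------------------------------------------

    def summary(self) -> str:
        """Human-readable fit summary in the spirit of statsmodels."""
        c = self.model.config
        m = self.metrics
        lines = [
            "Trait mapping results",
            "=" * 58,
            f"trait:              {c.trait}",
            f"resolution:         {c.resolution_km:g} km",
            f"data subset:        {c.subset}",
            f"training rows:      {len(self.model.table)}",
            f"CV folds used:      {len(self.cv.split_folds)}"
            + (f" (skipped: {self.cv.skipped_folds})" if self.cv.skipped_folds else ""),
            f"hexagons / range:   {self.folds.n_hexagons} @ {self.folds.range_km:.2f} km",
            f"fold balance (KS p):{self.folds.balance_score: .4f}",
            "-" * 58,
            f"pooled Pearson r:   {m.r: .4f}   (n = {m.n})",
            f"nRMSE ({m.nrmse_norm}):      {m.nrmse: .4f}",
            f"R^2:                {m.r2: .4f}",
        ]
        if self.cv.importance is not None:
            top = self.cv.importance["importance"].sort_values(ascending=False).head(5)
            lines.append("-" * 58)
            lines.append("top features (mean permutation importance):")
            for name, val in top.items():
                lines.append(f"  {name:<20s} {val: .5f}")
        lines.append("=" * 58)
        return "\n".join(lines)
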