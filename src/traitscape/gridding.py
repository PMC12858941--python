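"""Spatial aggregation of trait values and predictors onto equal-area grids.

Point-level trait values (plot CWMs and trait-tagged occurrences) are
aggregated to per-cell means at one or more resolutions; occurrence cells
are density-controlled by a min/max subsampling rule; survey and
occurrence grids can be merged with survey precedence; predictor stacks
are block-averaged to coarser grids; and labelled cells are joined with
predictors into a model-ready training table after a Yeo-Johnson power
transform of the labels and a predictor-completeness filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .grids import EnvironmentStack, GridSpec, assign_cells

__all__ = [
    "SOURCE_SURVEY",
    "SOURCE_OCCURRENCE",
    "TraitGrid",
    "TransformParams",
    "subsample_occurrences",
    "grid_trait_values",
    "merge_comb",
    "aggregate_predictors",
    "fit_transform",
    "apply_transform",
    "invert_transform",
    "build_training_table",
]

SOURCE_SURVEY = 1
SOURCE_OCCURRENCE = 2

# Default resolution ladder (cell edge lengths, km).
RESOLUTIONS_KM = (1.0, 22.0, 55.0, 111.0, 222.0)

# Occurrence density-control thresholds per grid cell.
MIN_OCC_PER_CELL = 10
MAX_OCC_PER_CELL = 500


@dataclass
class TraitGrid:
    """Per-cell trait statistic with provenance.

    ``values`` is NaN where unoccupied; ``counts`` is the number of
    contributing records; ``source`` is 0 (empty), ``SOURCE_SURVEY`` or
    ``SOURCE_OCCURRENCE``.
    """

    grid: GridSpec
    trait: str
    values: np.ndarray
    counts: np.ndarray
    source: np.ndarray

    def __post_init__(self) -> None:
        for arr in (self.values, self.counts, self.source):
            if arr.shape != self.grid.shape:
                raise ValueError("TraitGrid array shape mismatch")

    @property
    def occupied(self) -> np.ndarray:
        return self.source > 0

    @property
    def n_cells(self) -> int:
        return int(self.occupied.sum())


def subsample_occurrences(
    tagged: pd.DataFrame,
    grid: GridSpec,
    min_occ: int = MIN_OCC_PER_CELL,
    max_occ: int = MAX_OCC_PER_CELL,
    seed: int | None = None,
) -> pd.DataFrame:
    """Density-control tagged occurrences per grid cell.

    Cells holding fewer than ``min_occ`` records are dropped entirely
    (too sparse to estimate a frequency-weighted mean); cells holding
    more than ``max_occ`` are thinned to exactly ``max_occ`` by uniform
    sampling without replacement.  Applied independently at each
    resolution, before aggregation.
    """
    if not 1 <= min_occ <= max_occ:
        raise ValueError(f"need 1 <= min_occ <= max_occ, got ({min_occ}, {max_occ})")
    if tagged.empty:
        return tagged.copy()
    col, row, inside = assign_cells(tagged["x"].to_numpy(), tagged["y"].to_numpy(), grid)
    df = tagged[inside].copy()
    cell = row[inside] * grid.n_cols + col[inside]
    df["_cell"] = cell
    rng = np.random.default_rng(seed)

    keep_idx: list[np.ndarray] = []
    # iterate cells in sorted order so the draw sequence is reproducible
    for cell_id, group in df.groupby("_cell", sort=True):
        n = len(group)
        if n < min_occ:
            continue
        if n > max_occ:
            pos = rng.choice(n, size=max_occ, replace=False)
            keep_idx.append(group.index.to_numpy()[np.sort(pos)])
        else:
            keep_idx.append(group.index.to_numpy())
    if not keep_idx:
        return df.iloc[0:0].drop(columns="_cell")
    out = df.loc[np.concatenate(keep_idx)].drop(columns="_cell")
    return out


def grid_trait_values(
    rows: pd.DataFrame,
    grid: GridSpec,
    mode: str,
    trait: str | None = None,
    value_col: str | None = None,
) -> TraitGrid:
    """Aggregate point trait values to a per-cell mean grid.

    ``mode="fwm"`` consumes tagged occurrences (column ``value``) and
    produces frequency-weighted means; ``mode="cwm_mean"`` consumes plot
    CWMs (column ``cwm``) and produces mean CWM values.  Either way the
    cell statistic is the arithmetic mean of the records in the cell.
    """
    if mode not in ("fwm", "cwm_mean"):
        raise ValueError(f"mode must be 'fwm' or 'cwm_mean', got {mode!r}")
    source = SOURCE_OCCURRENCE if mode == "fwm" else SOURCE_SURVEY
    if value_col is None:
        value_col = "value" if mode == "fwm" else "cwm"
    if trait is None:
        trait = str(rows["trait"].iloc[0]) if ("trait" in rows and len(rows)) else "trait"

    values = np.full(grid.shape, np.nan)
    counts = np.zeros(grid.shape, dtype=np.int64)
    src = np.zeros(grid.shape, dtype=np.int8)
    if rows.empty:
        return TraitGrid(grid=grid, trait=trait, values=values, counts=counts, source=src)

    col, row, inside = assign_cells(rows["x"].to_numpy(), rows["y"].to_numpy(), grid)
    vals = rows[value_col].to_numpy(dtype=float)
    col, row, vals = col[inside], row[inside], vals[inside]

    np.add.at(counts, (row, col), 1)
    sums = np.zeros(grid.shape)
    np.add.at(sums, (row, col), vals)
    occupied = counts > 0
    values[occupied] = sums[occupied] / counts[occupied]
    src[occupied] = source
    return TraitGrid(grid=grid, trait=trait, values=values, counts=counts, source=src)


def merge_comb(cwm_grid: TraitGrid, fwm_grid: TraitGrid) -> TraitGrid:
    """Merge survey and occurrence grids with survey precedence.

    Cells occupied in the survey (CWM) grid keep their survey value;
    cells occupied only in the occurrence (FWM) grid take the FWM value;
    the merged occupancy is the union.
    """
    if cwm_grid.grid != fwm_grid.grid:
        raise ValueError("grids do not match")
    take_survey = cwm_grid.occupied
    take_occ = fwm_grid.occupied & ~take_survey
    values = np.where(take_survey, cwm_grid.values, np.where(take_occ, fwm_grid.values, np.nan))
    counts = np.where(take_survey, cwm_grid.counts, np.where(take_occ, fwm_grid.counts, 0))
    source = np.zeros(cwm_grid.grid.shape, dtype=np.int8)
    source[take_occ] = SOURCE_OCCURRENCE
    source[take_survey] = SOURCE_SURVEY
    return TraitGrid(
        grid=cwm_grid.grid,
        trait=cwm_grid.trait,
        values=values,
        counts=counts.astype(np.int64),
        source=source,
    )


def aggregate_predictors(env: EnvironmentStack, target: GridSpec) -> EnvironmentStack:
    """Block-average a predictor stack onto a coarser grid.

    Each target cell takes the mean of the source cells it covers,
    ignoring NaN (weights renormalised over the valid area); target cells
    with no valid source cell are NaN.  The target grid must share the
    origin and have an edge that is an integer multiple of the source
    edge (upsampling is unsupported).  Square cells on a shared origin
    make the overlap weights uniform, so the weighted mean reduces to a
    NaN-aware block mean.
    """
    src = env.grid
    if target.cell_edge < src.cell_edge:
        raise ValueError("target grid is finer than source; upsampling is unsupported")
    if (target.origin_x, target.origin_y) != (src.origin_x, src.origin_y):
        raise ValueError("grids must share an origin")
    k = int(round(target.cell_edge / src.cell_edge))
    if abs(target.cell_edge - k * src.cell_edge) > 1e-9:
        raise ValueError("target edge must be an integer multiple of source edge")
    if src.n_rows < target.n_rows * k or src.n_cols < target.n_cols * k:
        raise ValueError("target extent exceeds source extent")

    def block_mean(a: np.ndarray) -> np.ndarray:
        a = a[: target.n_rows * k, : target.n_cols * k]
        blocks = a.reshape(target.n_rows, k, target.n_cols, k)
        valid = np.isfinite(blocks)
        s = np.where(valid, blocks, 0.0).sum(axis=(1, 3))
        n = valid.sum(axis=(1, 3))
        out = np.full((target.n_rows, target.n_cols), np.nan)
        nz = n > 0
        out[nz] = s[nz] / n[nz]
        return out

    layers = {name: block_mean(arr) for name, arr in env.layers.items()}
    strata = None
    if env.strata is not None:
        # majority vote per block for the categorical layer
        a = env.strata[: target.n_rows * k, : target.n_cols * k]
        blocks = a.reshape(target.n_rows, k, target.n_cols, k)
        flat = blocks.transpose(0, 2, 1, 3).reshape(target.n_rows, target.n_cols, k * k)
        strata = np.apply_along_axis(lambda v: np.bincount(v).argmax(), 2, flat)
    return EnvironmentStack(grid=target, layers=layers, strata=strata)


@dataclass
class TransformParams:
    """Fitted Yeo-Johnson transform for one trait's label distribution.

    ``lmbda`` is the maximum-likelihood power parameter; optional
    post-transform standardisation stores the transformed-scale mean/sd.
    The fitted parameters are reused verbatim whenever held-out values or
    external products are brought onto the model's label scale.
    """

    trait: str
    lmbda: float
    mean: float = 0.0
    sd: float = 1.0
    standardize: bool = False

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "lambda": self.lmbda,
            "mean": self.mean,
            "sd": self.sd,
            "standardize": self.standardize,
        }


def fit_transform(
    values: np.ndarray, trait: str = "trait", standardize: bool = False
) -> TransformParams:
    """Fit the Yeo-Johnson power parameter by maximum likelihood."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2:
        raise ValueError("need at least two finite values to fit a transform")
    if np.ptp(v) == 0:
        # degenerate distribution: identity transform
        params = TransformParams(trait=trait, lmbda=1.0, standardize=False)
        return params
    _, lmbda = stats.yeojohnson(v)
    params = TransformParams(trait=trait, lmbda=float(lmbda), standardize=standardize)
    if standardize:
        t = apply_transform(v, params)
        params.mean = float(t.mean())
        params.sd = float(t.std()) or 1.0
    return params


def apply_transform(values: np.ndarray, params: TransformParams) -> np.ndarray:
    """Forward Yeo-Johnson transform with stored parameters."""
    x = np.asarray(values, dtype=float)
    if np.any(~np.isfinite(x) & ~np.isnan(x)):
        raise ValueError("non-finite (inf) inputs are rejected")
    out = stats.yeojohnson(x.ravel(), lmbda=params.lmbda).reshape(x.shape)
    if params.standardize:
        out = (out - params.mean) / params.sd
    return out


def invert_transform(values: np.ndarray, params: TransformParams) -> np.ndarray:
    """Inverse Yeo-Johnson transform (closed form)."""
    y = np.asarray(values, dtype=float)
    if params.standardize:
        y = y * params.sd + params.mean
    lm = params.lmbda
    out = np.empty_like(y)
    pos = y >= 0
    if abs(lm) > 1e-12:
        out[pos] = np.power(y[pos] * lm + 1.0, 1.0 / lm) - 1.0
    else:
        out[pos] = np.expm1(y[pos])
    neg = ~pos
    if abs(lm - 2.0) > 1e-12:
        out[neg] = 1.0 - np.power(-(2.0 - lm) * y[neg] + 1.0, 1.0 / (2.0 - lm))
    else:
        out[neg] = -np.expm1(-y[neg])
    return out


def build_training_table(
    label_grid: TraitGrid,
    env: EnvironmentStack,
    params: TransformParams,
    min_predictor_frac: float = 0.6,
) -> pd.DataFrame:
    """Join a labelled trait grid with predictors into a training table.

    One row per occupied label cell.  Rows whose cell has strictly fewer
    than ``min_predictor_frac`` of the predictors non-missing are
    excluded; remaining missing predictor values are kept as NaN (the
    learner tolerates them).  Labels are transformed with ``params``.

    Returns a DataFrame with columns ``cell_id, row, col, x, y, label,
    label_raw, source, stratum`` followed by one column per predictor.
    """
    if label_grid.grid != env.grid:
        raise ValueError("label grid and predictor stack must share a GridSpec")
    occ = label_grid.occupied
    rows, cols = np.nonzero(occ)
    if rows.size == 0:
        raise RuntimeError("label grid has no occupied cells")

    frac_ok = env.valid_fraction()[rows, cols] >= min_predictor_frac
    rows, cols = rows[frac_ok], cols[frac_ok]
    if rows.size == 0:
        raise RuntimeError(
            "no training rows survive the predictor-completeness filter "
            f"(threshold {min_predictor_frac:.0%}, {int((~frac_ok).sum())} cells dropped)"
        )

    g = label_grid.grid
    raw = label_grid.values[rows, cols]
    data = {
        "cell_id": rows * g.n_cols + cols,
        "row": rows,
        "col": cols,
        "x": g.origin_x + (cols + 0.5) * g.cell_edge,
        "y": g.origin_y + (rows + 0.5) * g.cell_edge,
        "label": apply_transform(raw, params),
        "label_raw": raw,
        "source": label_grid.source[rows, cols].astype(int),
        "stratum": (env.strata[rows, cols] if env.strata is not None else 0),
    }
    for name in env.layer_names:
        data[name] = env.layers[name][rows, cols]
    table = pd.DataFrame(data)
    if not np.all(np.isfinite(table["label"])):
        raise RuntimeError("non-finite labels after transformation")
    return table
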