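"""Spatially blocked cross-validation.

Random K-fold validation of geospatial models is optimistic: training and
validation points that are closer than the label's autocorrelation range
are near-duplicates.  The remedy implemented here is (1) estimate the
autocorrelation range of the survey CWM values with an empirical
semivariogram and a spherical-model fit, (2) tessellate the plane into
hexagons whose across-flats width equals that range, (3) assign hexagons
to K folds at random, repeated ``n_sim`` times, keeping the assignment
whose fold label distributions are most similar (maximal mean two-sample
Kolmogorov-Smirnov p-value over fold pairs), and (4) emit
leave-one-fold-out splits whose validation rows are survey-sourced only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import optimize, spatial, stats

logger = logging.getLogger(__name__)

__all__ = [
    "Variogram",
    "SphericalFit",
    "FoldAssignment",
    "empirical_variogram",
    "fit_spherical",
    "spherical_model",
    "hexagon_ids",
    "build_folds",
    "assign_rows_to_folds",
    "fold_summary",
    "hexagons_geojson",
    "loo_splits",
]


@dataclass
class Variogram:
    """Empirical (Matheron) semivariogram."""

    lags: np.ndarray  # bin centers, km
    gamma: np.ndarray  # semivariance per bin, value units^2
    counts: np.ndarray  # pairs per bin

    def __post_init__(self) -> None:
        keep = self.counts > 0
        self.lags = self.lags[keep]
        self.gamma = self.gamma[keep]
        self.counts = self.counts[keep]


def empirical_variogram(
    points: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    max_lag: float | None = None,
    max_pairs: int = 1_000_000,
    seed: int | None = None,
) -> Variogram:
    """Matheron estimator gamma(h) = sum (z_i - z_j)^2 / (2 N(h)).

    Pairs are enumerated exhaustively when their number fits in
    ``max_pairs``, otherwise that many pairs are sampled uniformly at
    random.  ``max_lag`` defaults to half the maximum point separation
    (the usual rule of thumb to avoid sparse long-range bins).
    """
    pts = np.asarray(points, dtype=float)
    z = np.asarray(values, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (n, 2)")
    n = len(pts)
    if n < 2:
        raise ValueError("need at least two points")

    n_all = n * (n - 1) // 2
    if n_all <= max_pairs:
        d = spatial.distance.pdist(pts)
        dz2 = spatial.distance.pdist(z[:, None], metric="sqeuclidean")
    else:
        rng = np.random.default_rng(seed)
        i = rng.integers(0, n, size=max_pairs)
        j = rng.integers(0, n, size=max_pairs)
        keep = i != j
        i, j = i[keep], j[keep]
        d = np.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
        dz2 = (z[i] - z[j]) ** 2

    if max_lag is None:
        max_lag = float(d.max()) / 2.0
    if max_lag <= 0:
        raise ValueError("all points are coincident: variogram is undefined")

    inside = d <= max_lag
    d, dz2 = d[inside], dz2[inside]
    edges = np.linspace(0.0, max_lag, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=dz2, minlength=n_bins)
    gamma = np.zeros(n_bins)
    nz = counts > 0
    gamma[nz] = sums[nz] / (2.0 * counts[nz])
    centers = 0.5 * (edges[:-1] + edges[1:])
    return Variogram(lags=centers, gamma=gamma, counts=counts)


def spherical_model(h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    """Spherical semivariogram model, flat at nugget + psill beyond the range."""
    h = np.asarray(h, dtype=float)
    hr = np.minimum(h / rng, 1.0)
    return nugget + psill * (1.5 * hr - 0.5 * hr**3)


@dataclass
class SphericalFit:
    """Weighted least-squares spherical-model parameters."""

    nugget: float
    psill: float
    range_km: float
    rmse: float
    flagged: bool = False  # True when the range was unidentifiable

    @property
    def sill(self) -> float:
        return self.nugget + self.psill


def fit_spherical(vg: Variogram) -> SphericalFit:
    """Fit the spherical model by pair-count-weighted least squares.

    A flat (pure-nugget) variogram leaves the range unidentifiable; in
    that case the range is pinned to the largest observed lag and the fit
    is flagged, with a loud warning, rather than failing.
    """
    if len(vg.lags) < 3:
        raise ValueError("need at least three variogram bins to fit")
    h, g, w = vg.lags, vg.gamma, np.sqrt(vg.counts.astype(float))
    max_lag = float(h.max())
    gmax = float(g.max())

    if gmax <= 0:  # constant values: zero variogram
        return SphericalFit(0.0, 0.0, max_lag, 0.0, flagged=True)

    def resid(p):
        return w * (spherical_model(h, *p) - g)

    best = None
    # a few starts guard against the local minima of the cubic section
    for r0 in (max_lag / 4, max_lag / 2, max_lag):
        p0 = (max(g[0], 0.0), max(gmax - g[0], 1e-12 * gmax), r0)
        try:
            sol = optimize.least_squares(
                resid,
                p0,
                # the range is capped at the largest observed lag: beyond it
                # the data carry no curvature to identify it
                bounds=([0.0, 0.0, 1e-12], [np.inf, np.inf, max_lag]),
                xtol=1e-14,
                ftol=1e-14,
                gtol=1e-14,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        logger.warning("spherical fit failed to converge; falling back to max lag range")
        return SphericalFit(float(np.average(g, weights=w**2)), 0.0, max_lag, np.nan, flagged=True)

    nugget, psill, rng_km = best.x
    rmse = float(np.sqrt(np.mean((spherical_model(h, *best.x) - g) ** 2)))
    if rng_km >= 0.999 * max_lag:
        logger.warning(
            "fitted range reaches the largest observed lag (%.3g km): the true "
            "range is at or beyond the observable scale",
            max_lag,
        )
        return SphericalFit(float(nugget), float(psill), max_lag, rmse, flagged=True)
    if psill <= 1e-6 * (nugget + psill):
        logger.warning(
            "variogram is flat (pure nugget): range unidentifiable, pinned to max lag %.3g km",
            max_lag,
        )
        return SphericalFit(float(nugget), float(psill), max_lag, rmse, flagged=True)
    return SphericalFit(float(nugget), float(psill), float(rng_km), rmse)


# -- hexagonal tessellation ------------------------------------------------

_HEX_OFFSET = 1 << 15


def hexagon_ids(points: np.ndarray, width_km: float) -> np.ndarray:
    """Assign points to flat-top hexagons of the given across-flats width.

    Uses axial coordinates with cube rounding; the returned id encodes
    the (q, r) pair of the containing hexagon.
    """
    if width_km <= 0:
        raise ValueError("hexagon width must be > 0")
    pts = np.asarray(points, dtype=float)
    size = width_km / np.sqrt(3.0)  # circumradius of a flat-top hexagon
    qf = (2.0 / 3.0) * pts[:, 0] / size
    rf = (-1.0 / 3.0) * pts[:, 0] / size + (np.sqrt(3.0) / 3.0) * pts[:, 1] / size
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq, dr, ds = np.abs(q - qf), np.abs(r - rf), np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    qi = q.astype(np.int64) + _HEX_OFFSET
    ri = r.astype(np.int64) + _HEX_OFFSET
    if np.any((qi < 0) | (ri < 0) | (qi >= 1 << 16) | (ri >= 1 << 16)):
        raise ValueError("points too far from origin for hexagon id encoding")
    return qi * (1 << 16) + ri


@dataclass
class FoldAssignment:
    """Hexagon-to-fold mapping chosen by the KS balancing procedure."""

    K: int
    hex_to_fold: dict[int, int]
    hex_id: np.ndarray  # per input row
    fold: np.ndarray  # per input row, in 1..K
    balance_score: float
    candidate_scores: np.ndarray
    range_km: float

    @property
    def n_hexagons(self) -> int:
        return len(self.hex_to_fold)


def _mean_ks_p(values: np.ndarray, folds: np.ndarray, K: int) -> float:
    ps = []
    by_fold = [values[folds == k] for k in range(1, K + 1)]
    for a, b in combinations(range(K), 2):
        va, vb = by_fold[a], by_fold[b]
        if len(va) < 2 or len(vb) < 2:
            ps.append(0.0)  # an (almost) empty fold is maximally unbalanced
            continue
        ps.append(float(stats.ks_2samp(va, vb, method="auto").pvalue))
    return float(np.mean(ps))


def build_folds(
    points: np.ndarray,
    values: np.ndarray,
    range_km: float,
    K: int = 5,
    n_sim: int = 100,
    seed: int | None = None,
) -> FoldAssignment:
    """KS-balanced random assignment of range-sized hexagons to K folds.

    The tessellation is fixed; ``n_sim`` independent uniform assignments
    of hexagons to folds are scored by the mean two-sample KS p-value
    over all fold pairs of the row values, and the best-scoring
    assignment is returned.  Hexagons are sized so their across-flats
    width equals ``range_km``, separating folds at (or beyond) the
    autocorrelation range.
    """
    if range_km <= 0:
        raise ValueError("range_km must be > 0")
    pts = np.asarray(points, dtype=float)
    vals = np.asarray(values, dtype=float)
    hex_id = hexagon_ids(pts, range_km)
    uniq, inverse = np.unique(hex_id, return_inverse=True)
    if len(uniq) < K:
        raise ValueError(
            f"only {len(uniq)} hexagons for K={K} folds; enlarge the domain or "
            "reduce the hexagon size"
        )
    rng = np.random.default_rng(seed)
    candidates = [rng.integers(1, K + 1, size=len(uniq)) for _ in range(n_sim)]
    scores = np.array([_mean_ks_p(vals, c[inverse], K) for c in candidates])
    best = int(np.argmax(scores))  # first occurrence wins ties
    best_assign = candidates[best]
    best_folds = best_assign[inverse]
    return FoldAssignment(
        K=K,
        hex_to_fold={int(h): int(f) for h, f in zip(uniq, best_assign)},
        hex_id=hex_id,
        fold=best_folds,
        balance_score=float(scores[best]),
        candidate_scores=scores,
        range_km=range_km,
    )


def hexagon_center(hex_id: int, width_km: float) -> tuple[float, float]:
    """Planar center of the hexagon encoded by ``hex_id``."""
    size = width_km / np.sqrt(3.0)
    q = (hex_id >> 16) - _HEX_OFFSET
    r = (hex_id & 0xFFFF) - _HEX_OFFSET
    return 1.5 * size * q, np.sqrt(3.0) * size * (r + q / 2.0)


def fold_summary(assignment: "FoldAssignment") -> pd.DataFrame:
    """One row per hexagon: id, centroid, and assigned fold."""
    rows = []
    for h, f in assignment.hex_to_fold.items():
        cx, cy = hexagon_center(h, assignment.range_km)
        rows.append({"hex_id": h, "centroid_x": cx, "centroid_y": cy, "fold": f})
    return pd.DataFrame(rows)


def hexagons_geojson(assignment: "FoldAssignment") -> dict:
    """GeoJSON-style FeatureCollection of the fold hexagons for inspection."""
    size = assignment.range_km / np.sqrt(3.0)
    angles = np.deg2rad(np.arange(0, 360, 60))
    features = []
    for h, f in assignment.hex_to_fold.items():
        cx, cy = hexagon_center(h, assignment.range_km)
        ring = [[cx + size * np.cos(a), cy + size * np.sin(a)] for a in angles]
        ring.append(ring[0])
        features.append(
            {
                "type": "Feature",
                "properties": {"hex_id": int(h), "fold": int(f)},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def assign_rows_to_folds(
    points: np.ndarray, assignment: FoldAssignment
) -> np.ndarray:
    """Fold of each new row via its hexagon; unseen hexagons get fold 0.

    Rows in hexagons that held no labelled data when the folds were built
    (fold 0) take part in no split.
    """
    hex_id = hexagon_ids(np.asarray(points, dtype=float), assignment.range_km)
    return np.array([assignment.hex_to_fold.get(int(h), 0) for h in hex_id])


def loo_splits(
    table: pd.DataFrame,
    fold: np.ndarray,
    source: np.ndarray | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Leave-one-fold-out splits with survey-only validation rows.

    Returns one ``(train_idx, val_idx)`` pair of positional indices per
    fold.  Training rows are all rows outside the held-out fold (any
    source); validation rows are the held-out fold's survey-sourced rows.
    Folds without survey rows are skipped with a warning.
    """
    from .gridding import SOURCE_SURVEY

    fold = np.asarray(fold)
    if len(fold) != len(table):
        raise ValueError("fold vector length does not match table")
    if source is None:
        source = table["source"].to_numpy()
    source = np.asarray(source)

    splits = []
    for k in sorted(set(fold[fold > 0])):
        val = np.flatnonzero((fold == k) & (source == SOURCE_SURVEY))
        train = np.flatnonzero(fold != k)
        if len(val) == 0:
            logger.warning("fold %d holds no survey rows; split skipped", k)
            continue
        splits.append((train, val))
    if not splits:
        raise RuntimeError("no usable validation folds (no survey rows anywhere)")
    return splits
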