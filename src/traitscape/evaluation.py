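"""Validation metrics and cross-variant comparison tables.

All scores are computed on the pooled observed-versus-predicted pairs of
every cross-validation split (pooling before scoring, so folds with more
validation plots weigh proportionally).  Pearson's r is the primary
metric; nRMSE (RMSE divided by the observed range) and R-squared
(1 - SSE/SST) are reported alongside, never alone, because R-squared is
sensitive to differences in trait variance between regions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["MetricsReport", "compute_metrics", "compare_variants"]

#: Supported nRMSE normalisations; range is the reporting default.
NRMSE_NORMS = ("range", "mean", "iqr")


@dataclass
class MetricsReport:
    """Pooled and per-stratum validation scores for one model task."""

    trait: str
    resolution_km: float
    subset: str
    r: float
    rmse: float
    nrmse: float
    r2: float
    n: int
    nrmse_norm: str = "range"
    per_stratum: pd.DataFrame | None = None
    # fold-wise means (scored per CV split, then averaged) accompany the
    # pooled scores when the split structure is known
    r_foldwise_mean: float = np.nan
    nrmse_foldwise_mean: float = np.nan

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "resolution_km": self.resolution_km,
            "subset": self.subset,
            "r": self.r,
            "rmse": self.rmse,
            "nrmse": self.nrmse,
            "r2": self.r2,
            "n": self.n,
            "nrmse_norm": self.nrmse_norm,
            "r_foldwise_mean": self.r_foldwise_mean,
            "nrmse_foldwise_mean": self.nrmse_foldwise_mean,
        }


def _scores(obs: np.ndarray, pred: np.ndarray, nrmse_norm: str) -> tuple[float, float, float, float]:
    if len(obs) > 1 and np.ptp(obs) > 0 and np.ptp(pred) > 0:
        r = float(stats.pearsonr(obs, pred).statistic)
    else:
        r = np.nan  # correlation undefined for constant vectors
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if nrmse_norm == "range":
        denom = float(np.ptp(obs))
    elif nrmse_norm == "mean":
        denom = float(np.abs(obs.mean()))
    else:
        q25, q75 = np.quantile(obs, [0.25, 0.75])
        denom = float(q75 - q25)
    nrmse = rmse / denom if denom > 0 else np.nan
    sst = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - float(np.sum((obs - pred) ** 2)) / sst if sst > 0 else np.nan
    return r, rmse, nrmse, r2


def compute_metrics(
    observed: np.ndarray,
    predicted: np.ndarray,
    strata: np.ndarray | None = None,
    trait: str = "trait",
    resolution_km: float = np.nan,
    subset: str = "COMB",
    nrmse_norm: str = "range",
    split_sizes: list[int] | None = None,
) -> MetricsReport:
    """Score pooled observed-versus-predicted validation pairs.

    A zero observed range leaves nRMSE undefined (NaN, flagged by the
    report rather than raising).  Per-stratum scores repeat the pooled
    computation within each stratum with its own n.
    """
    if nrmse_norm not in NRMSE_NORMS:
        raise ValueError(f"nrmse_norm must be one of {NRMSE_NORMS}")
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < 2:
        raise ValueError("need at least two validation pairs")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values in observed/predicted")

    r, rmse, nrmse, r2 = _scores(obs, pred, nrmse_norm)

    per_stratum = None
    if strata is not None:
        strata = np.asarray(strata)
        rows = []
        for s in np.unique(strata):
            m = strata == s
            if m.sum() < 2:
                continue
            rs, rmses, nrmses, r2s = _scores(obs[m], pred[m], nrmse_norm)
            rows.append({"stratum": s, "r": rs, "rmse": rmses, "nrmse": nrmses,
                         "r2": r2s, "n": int(m.sum())})
        per_stratum = pd.DataFrame(rows)

    r_fw = nrmse_fw = np.nan
    if split_sizes and sum(split_sizes) == obs.size and len(split_sizes) > 1:
        edges = np.cumsum([0] + list(split_sizes))
        parts = [
            _scores(obs[a:b], pred[a:b], nrmse_norm)
            for a, b in zip(edges[:-1], edges[1:])
            if b - a >= 2
        ]
        if parts:
            r_fw = float(np.nanmean([p[0] for p in parts]))
            nrmse_fw = float(np.nanmean([p[2] for p in parts]))

    return MetricsReport(
        trait=trait, resolution_km=resolution_km, subset=subset,
        r=r, rmse=rmse, nrmse=nrmse, r2=r2, n=int(obs.size),
        nrmse_norm=nrmse_norm, per_stratum=per_stratum,
        r_foldwise_mean=r_fw, nrmse_foldwise_mean=nrmse_fw,
    )


def compare_variants(
    reports: dict[str, MetricsReport],
    uncertainty: dict[str, "object"] | None = None,
    pairs: list[tuple[str, str]] = (("COMB", "SCI"), ("COMB", "CIT")),
) -> pd.DataFrame:
    """Deltas of r, nRMSE, mean COV and AOA coverage between subsets.

    ``reports`` maps subset name to its MetricsReport; ``uncertainty``
    optionally maps subset name to an UncertaintyProduct.  All reports
    must describe the same trait and resolution.
    """
    keys = list(reports)
    ref = reports[keys[0]]
    for k in keys[1:]:
        rep = reports[k]
        if rep.trait != ref.trait or not np.isclose(rep.resolution_km, ref.resolution_km, equal_nan=True):
            raise ValueError(
                f"variant {k!r} describes ({rep.trait}, {rep.resolution_km}), "
                f"expected ({ref.trait}, {ref.resolution_km})"
            )
    rows = []
    for a, b in pairs:
        if a not in reports or b not in reports:
            continue
        row = {
            "pair": f"{a}-{b}",
            "delta_r": reports[a].r - reports[b].r,
            "delta_nrmse": reports[a].nrmse - reports[b].nrmse,
        }
        if uncertainty and a in uncertainty and b in uncertainty:
            ua, ub = uncertainty[a], uncertainty[b]
            row["delta_mean_cov"] = float(np.nanmean(ua.cov) - np.nanmean(ub.cov))
            row["delta_aoa_pct"] = ua.percent_inside - ub.percent_inside
        rows.append(row)
    return pd.DataFrame(rows)
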