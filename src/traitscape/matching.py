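"""Species-name matching and trait assignment.

Observation, survey and trait tables rarely share identical species
strings: authority suffixes, infraspecific epithets and case differences
break naive joins.  Matching here is deliberately blunt — names are
truncated to their first two whitespace-delimited words and lowercased,
and tables are joined on that normalised binomial.  Species with no trait
record are dropped (with their cover mass renormalised by default), and
the retention bookkeeping is reported so the cost of the coverage gap is
visible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "normalize_name",
    "normalize_names",
    "species_means",
    "plot_cwm",
    "tag_occurrences",
    "MatchReport",
]


def normalize_name(raw_name: str) -> str | None:
    """Normalise a species string to its two-word lowercase binomial.

    Takes the first two whitespace-delimited tokens and lowercases them,
    stripping authority suffixes and infraspecific epithets in the
    process.  Single-token names cannot form a binomial and return None
    (flagged unmatched, never padded or guessed).
    """
    if raw_name is None or not str(raw_name).strip():
        raise ValueError("species name must be non-empty")
    tokens = str(raw_name).split()
    if len(tokens) < 2:
        return None
    return f"{tokens[0].lower()} {tokens[1].lower()}"


def normalize_names(names: pd.Series) -> pd.Series:
    """Vectorised :func:`normalize_name`; single-token names become NaN."""
    s = names.astype(str).str.strip()
    if (s == "").any():
        raise ValueError("species name must be non-empty")
    parts = s.str.split()
    out = parts.map(lambda t: f"{t[0].lower()} {t[1].lower()}" if len(t) >= 2 else None)
    return out


@dataclass
class MatchReport:
    """Retention bookkeeping from a matching step."""

    n_input: int = 0
    n_retained: int = 0
    n_dropped: int = 0
    n_species_input: int = 0
    n_species_matched: int = 0
    renormalized: bool = True
    dropped_plots: int = 0

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_dropped": self.n_dropped,
            "retained_fraction": self.n_retained / self.n_input if self.n_input else None,
            "n_species_input": self.n_species_input,
            "n_species_matched": self.n_species_matched,
            "renormalized": self.renormalized,
            "dropped_plots": self.dropped_plots,
        }


def species_means(db: pd.DataFrame) -> pd.DataFrame:
    """Species-level mean trait values from a measurement table.

    Parameters
    ----------
    db : table with columns ``species, trait, value`` (one row per
        measurement; names may carry authority noise).

    Returns
    -------
    Table indexed by ``(species, trait)`` with columns ``mean`` and
    ``count``, species already normalised to lowercase binomials.
    Non-finite measurements and un-normalisable names are rejected row
    by row with a logged warning.
    """
    if db.empty:
        raise ValueError("trait measurement table is empty")
    db = db.copy()
    db["species"] = normalize_names(db["species"])
    bad_name = db["species"].isna()
    bad_value = ~np.isfinite(db["value"].to_numpy(dtype=float))
    n_bad = int((bad_name | bad_value).sum())
    if n_bad:
        logger.warning("species_means: rejected %d rows (bad name or non-finite value)", n_bad)
        db = db[~(bad_name | bad_value)]
    if db.empty:
        raise ValueError("no valid trait measurements after filtering")
    out = (
        db.groupby(["species", "trait"])["value"]
        .agg(mean="mean", count="size")
        .reset_index()
    )
    out["count"] = out["count"].astype(int)
    return out.set_index(["species", "trait"])


def _trait_lookup(means: pd.DataFrame, trait_name: str) -> pd.Series:
    sub = means.xs(trait_name, level="trait")["mean"]
    if sub.empty:
        raise KeyError(f"trait {trait_name!r} absent from species means table")
    return sub


def plot_cwm(
    surveys: pd.DataFrame,
    means: pd.DataFrame,
    trait_name: str,
    renormalize: bool = True,
) -> tuple[pd.DataFrame, MatchReport]:
    """Community-weighted mean trait per survey plot.

    CWM = sum(cover_s * mean_s) / sum(cover_s) over trait-matched species.
    Unmatched species are removed; by default the remaining cover weights
    are renormalised (``renormalize=False`` keeps the raw covers as
    weights, treating unmatched cover as missing rather than rescaled —
    both conventions give identical results whenever covers are later
    normalised, and the report records which was used).  Plots with zero
    matched cover are dropped.

    Returns
    -------
    (table, report) — table with columns ``plot_id, x, y, trait, cwm,
    matched_cover`` and the retention report.
    """
    if trait_name not in means.index.get_level_values("trait"):
        raise KeyError(f"trait {trait_name!r} absent from species means table")
    lookup = _trait_lookup(means, trait_name)

    sv = surveys.copy()
    sv["_binomial"] = normalize_names(sv["species"])
    sv["_trait"] = sv["_binomial"].map(lookup)
    matched = sv["_trait"].notna()

    report = MatchReport(
        n_input=len(sv),
        n_retained=int(matched.sum()),
        n_dropped=int((~matched).sum()),
        n_species_input=sv["_binomial"].nunique(),
        n_species_matched=sv.loc[matched, "_binomial"].nunique(),
        renormalized=renormalize,
    )

    kept = sv[matched]
    if kept.empty:
        report.dropped_plots = sv["plot_id"].nunique()
        empty = pd.DataFrame(columns=["plot_id", "x", "y", "trait", "cwm", "matched_cover"])
        return empty, report

    def agg(group: pd.DataFrame) -> pd.Series:
        cover = group["relative_cover"].to_numpy(dtype=float)
        tvals = group["_trait"].to_numpy(dtype=float)
        wsum = cover.sum()
        cwm = (cover * tvals).sum() / wsum if renormalize else (cover * tvals).sum()
        return pd.Series(
            {
                "x": group["x"].iloc[0],
                "y": group["y"].iloc[0],
                "cwm": cwm,
                "matched_cover": wsum,
            }
        )

    table = kept.groupby("plot_id", sort=True).apply(agg, include_groups=False).reset_index()
    # plots whose matched cover is numerically zero carry no information
    nonzero = table["matched_cover"] > 0
    report.dropped_plots = int((~nonzero).sum()) + (
        surveys["plot_id"].nunique() - table["plot_id"].nunique()
    )
    table = table[nonzero].copy()
    table["trait"] = trait_name
    return table[["plot_id", "x", "y", "trait", "cwm", "matched_cover"]], report


def tag_occurrences(
    occ: pd.DataFrame, means: pd.DataFrame, trait_name: str
) -> tuple[pd.DataFrame, MatchReport]:
    """Attach species-mean trait values to occurrence records.

    Unmatched records are dropped and counted.  Returns columns
    ``record_id, x, y, trait, value``.
    """
    lookup = _trait_lookup(means, trait_name)
    oc = occ.copy()
    oc["_binomial"] = normalize_names(oc["species"])
    oc["value"] = oc["_binomial"].map(lookup)
    matched = oc["value"].notna()
    report = MatchReport(
        n_input=len(oc),
        n_retained=int(matched.sum()),
        n_dropped=int((~matched).sum()),
        n_species_input=oc["_binomial"].nunique(),
        n_species_matched=oc.loc[matched, "_binomial"].nunique(),
    )
    out = oc.loc[matched, ["record_id", "x", "y", "value"]].copy()
    out.insert(3, "trait", trait_name)
    return out.reset_index(drop=True), report
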