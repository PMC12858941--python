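"""Synthetic miniature world with known ground truth.

Generates the four inputs the trait-mapping pipeline consumes — an
environmental predictor stack, clustered vegetation-survey plots with
relative species cover, spatially biased opportunistic occurrence records,
and an incomplete trait-measurement database — from a latent community
field whose trait structure is fully known.  Every sampler is driven by a
:class:`numpy.random.Generator` seed and is bit-reproducible.

The world model, in brief:

* environment layers are stationary Gaussian random fields built by
  kernel-smoothing white noise, with the smoothing bandwidth calibrated so
  the empirical semivariogram range of the output matches a requested
  autocorrelation range;
* each species responds to one or more environment axes through an
  independent Gaussian niche, and per-cell relative covers are the
  renormalised niche responses;
* species trait values are drawn from configurable distributions and may
  be linked linearly to a niche optimum, which is what makes the
  community-weighted mean (CWM) trait surface a learnable function of the
  environment;
* surveys record the full (or top-k truncated) community of their cell,
  occurrences are single records drawn proportionally to
  effort x cover x detectability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .grids import EnvironmentStack, GridSpec, assign_cells

__all__ = [
    "ClusterSpec",
    "SpeciesPool",
    "CommunityField",
    "generate_environment",
    "generate_species_pool",
    "simulate_communities",
    "sample_surveys",
    "sample_occurrences",
    "subset_trait_db",
    "true_cwm_surface",
]

# Ratio between the spherical-model range fitted to a Gaussian-kernel
# smoothed field and the kernel sigma.  For white noise smoothed with a
# Gaussian kernel of sd sigma, the field correlation is
# rho(h) = exp(-h^2 / (4 sigma^2)); calibrated against this package's own
# variogram estimator (weighted least squares, 15 bins, lag cap at ~2.5x
# the range) the fitted spherical range comes out near 4.45 sigma.
_RANGE_PER_SIGMA = 4.45

_GENUS_SYLLABLES = [
    "ab", "cal", "den", "er", "fag", "gera", "hel", "iso", "jun", "kar",
    "lam", "myr", "nar", "oxa", "pin", "quer", "ros", "sal", "tri", "ulm",
]
_EPITHET_SYLLABLES = [
    "alba", "bora", "cana", "dora", "ensis", "flora", "gale", "hirta",
    "ica", "jata", "kora", "lata", "mica", "nana", "osa", "pila", "rica",
    "sora", "tica", "vera",
]


def _make_binomials(n: int, rng: np.random.Generator) -> list[str]:
    """Unique plausible two-word lowercase binomials."""
    names: list[str] = []
    seen: set[str] = set()
    while len(names) < n:
        g = "".join(rng.choice(_GENUS_SYLLABLES, size=2))
        e = "".join(rng.choice(_EPITHET_SYLLABLES, size=2))
        name = f"{g} {e}"
        if name not in seen:
            seen.add(name)
            names.append(name)
    return names


def generate_environment(
    grid: GridSpec,
    layer_names: list[str],
    autocorr_range_km: float,
    noise_sd: float = 1.0,
    seed: int | None = None,
    base: float | dict[str, float] = 0.0,
    n_strata: int = 0,
) -> EnvironmentStack:
    """Simulate spatially autocorrelated predictor layers.

    Each layer is white noise smoothed with a Gaussian kernel (wrapped
    boundaries, so the field is stationary on the torus), standardised to
    unit variance, scaled by ``noise_sd`` and shifted by ``base``.  The
    kernel bandwidth is calibrated so a spherical semivariogram fitted to
    the realised field recovers approximately ``autocorr_range_km``.

    Parameters
    ----------
    grid : target grid.
    layer_names : names of the independent layers to generate.
    autocorr_range_km : requested semivariogram range, km (> 0).
    noise_sd : marginal standard deviation of each layer.
    seed : RNG seed; required for reproducibility.
    base : constant offset, scalar or per-layer mapping.
    n_strata : if > 0, also generate a categorical stratum layer by
        quantile-slicing an extra autocorrelated field into ``n_strata``
        contiguous regions (a stand-in for biome categories).
    """
    if autocorr_range_km <= 0:
        raise ValueError(f"autocorr_range_km must be > 0, got {autocorr_range_km}")
    if not layer_names:
        raise ValueError("layer_names must be non-empty")
    if len(set(layer_names)) != len(layer_names):
        raise ValueError("layer_names must be unique")

    rng = np.random.default_rng(seed)
    sigma_cells = autocorr_range_km / _RANGE_PER_SIGMA / grid.cell_edge

    def one_field() -> np.ndarray:
        z = rng.standard_normal(grid.shape)
        if sigma_cells > 0:
            z = ndimage.gaussian_filter(z, sigma=sigma_cells, mode="wrap")
        sd = z.std()
        if sd > 0:
            z = (z - z.mean()) / sd
        return z

    layers = {}
    for name in layer_names:
        b = base[name] if isinstance(base, dict) else base
        layers[name] = b + noise_sd * one_field()

    strata = None
    if n_strata > 0:
        f = one_field()
        edges = np.quantile(f, np.linspace(0, 1, n_strata + 1)[1:-1])
        strata = np.digitize(f, edges)
    return EnvironmentStack(grid=grid, layers=layers, strata=strata)


@dataclass
class SpeciesPool:
    """The synthetic truth: species, their traits, and their niches.

    Attributes
    ----------
    binomials : unique two-word lowercase names, one per species.
    traits : per-species true trait values, one column per trait,
        indexed by binomial.
    niche_optima, niche_breadths : per-species niche parameters, one
        column per environment axis, indexed by binomial.
    """

    binomials: list[str]
    traits: pd.DataFrame
    niche_optima: pd.DataFrame
    niche_breadths: pd.DataFrame

    @property
    def n_species(self) -> int:
        return len(self.binomials)

    @property
    def trait_names(self) -> list[str]:
        return list(self.traits.columns)

    @property
    def niche_axes(self) -> list[str]:
        return list(self.niche_optima.columns)


def generate_species_pool(
    n_species: int,
    trait_specs: dict[str, dict] | list[tuple[str, dict]],
    niche_spec: dict[str, dict],
    seed: int | None = None,
) -> SpeciesPool:
    """Draw a species pool with niches and (possibly niche-linked) traits.

    ``trait_specs`` maps trait name to a distribution spec:

    * ``{"dist": "lognormal", "mu": m, "sigma": s}``
    * ``{"dist": "normal", "mean": m, "sd": s}``
    * ``{"dist": "constant", "value": v}``
    * ``{"dist": "linked", "axis": a, "intercept": b0, "slope": b1,
      "noise_sd": s}`` — trait = b0 + b1 * niche_optimum(a) + N(0, s);
      this is the switch that plants a recoverable trait-environment
      signal in the world.

    ``niche_spec`` maps environment-axis name to
    ``{"optimum_range": (lo, hi), "breadth_range": (lo, hi)}``; optima are
    uniform over the range, breadths log-uniform.
    """
    if n_species < 2:
        raise ValueError("n_species must be >= 2")
    if not isinstance(trait_specs, dict):
        names = [n for n, _ in trait_specs]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate trait names in trait_specs: {names}")
        trait_specs = dict(trait_specs)
    if not trait_specs:
        raise ValueError("at least one trait spec is required")

    rng = np.random.default_rng(seed)
    binomials = _make_binomials(n_species, rng)

    optima = {}
    breadths = {}
    for axis, spec in niche_spec.items():
        lo, hi = spec["optimum_range"]
        optima[axis] = rng.uniform(lo, hi, n_species)
        blo, bhi = spec["breadth_range"]
        if blo <= 0:
            raise ValueError(f"niche breadth must be > 0 on axis {axis!r}")
        breadths[axis] = np.exp(rng.uniform(np.log(blo), np.log(bhi), n_species))
    optima_df = pd.DataFrame(optima, index=binomials)
    breadths_df = pd.DataFrame(breadths, index=binomials)

    traits = {}
    for name, spec in trait_specs.items():
        dist = spec["dist"]
        if dist == "lognormal":
            traits[name] = rng.lognormal(spec["mu"], spec["sigma"], n_species)
        elif dist == "normal":
            traits[name] = rng.normal(spec["mean"], spec["sd"], n_species)
        elif dist == "constant":
            traits[name] = np.full(n_species, float(spec["value"]))
        elif dist == "linked":
            axis = spec["axis"]
            if axis not in optima:
                raise ValueError(f"linked trait {name!r} references unknown axis {axis!r}")
            noise = rng.normal(0.0, spec.get("noise_sd", 0.0), n_species)
            traits[name] = spec["intercept"] + spec["slope"] * optima[axis] + noise
        else:
            raise ValueError(f"unknown trait distribution {dist!r}")
        if not np.all(np.isfinite(traits[name])):
            raise ValueError(f"non-finite trait values generated for {name!r}")
    traits_df = pd.DataFrame(traits, index=binomials)

    return SpeciesPool(
        binomials=binomials,
        traits=traits_df,
        niche_optima=optima_df,
        niche_breadths=breadths_df,
    )


@dataclass
class CommunityField:
    """Latent per-cell relative covers for each species.

    ``cover`` has shape ``(n_species, n_rows, n_cols)``; occupied cells
    sum to 1 over species, empty cells sum to 0.
    """

    grid: GridSpec
    binomials: list[str]
    cover: np.ndarray

    def __post_init__(self) -> None:
        expected = (len(self.binomials),) + self.grid.shape
        if self.cover.shape != expected:
            raise ValueError(f"cover shape {self.cover.shape} != {expected}")

    @property
    def occupied(self) -> np.ndarray:
        """Boolean mask of cells holding a community."""
        return self.cover.sum(axis=0) > 0.5  # sums are exactly 0 or 1


def simulate_communities(
    env: EnvironmentStack,
    pool: SpeciesPool,
    absence_floor: float = 1e-4,
) -> CommunityField:
    """Turn niche responses into relative-cover communities.

    The response of species *s* in a cell is the product over niche axes
    of ``exp(-(env_a - optimum)^2 / (2 breadth^2))``.  Responses below
    ``absence_floor`` are treated as absence; remaining responses are
    renormalised to sum to 1.  Cells where every species is absent (or
    where a niche-axis layer is missing) are left empty.
    """
    for axis in pool.niche_axes:
        if axis not in env.layers:
            raise KeyError(f"niche axis {axis!r} not present in environment layers")

    n = pool.n_species
    log_resp = np.zeros((n,) + env.grid.shape)
    for axis in pool.niche_axes:
        layer = env.layers[axis]
        opt = pool.niche_optima[axis].to_numpy()[:, None, None]
        br = pool.niche_breadths[axis].to_numpy()[:, None, None]
        log_resp = log_resp - (layer[None] - opt) ** 2 / (2.0 * br**2)
    resp = np.exp(log_resp)
    resp[~np.isfinite(resp)] = 0.0
    resp[resp < absence_floor] = 0.0
    total = resp.sum(axis=0)
    occupied = total > 0
    cover = np.where(occupied[None], resp / np.where(occupied, total, 1.0)[None], 0.0)
    return CommunityField(grid=env.grid, binomials=list(pool.binomials), cover=cover)


@dataclass
class ClusterSpec:
    """Clustered (Thomas-process-like) plot placement.

    ``n_clusters`` parent centers are placed uniformly over the extent
    (or given explicitly via ``centers``); each plot picks a parent
    uniformly and lands at a Gaussian offset with sd ``dispersion_km``.
    """

    n_clusters: int = 5
    dispersion_km: float = 10.0
    centers: np.ndarray | None = None


def sample_surveys(
    comm: CommunityField,
    n_plots: int,
    cluster_spec: ClusterSpec | None = None,
    seed: int | None = None,
    top_k: int | None = None,
    unique_cells: bool = False,
) -> pd.DataFrame:
    """Place survey plots and record their cell communities.

    Returns a long-format table with columns ``plot_id, x, y, species,
    relative_cover``.  Each plot records the complete relative covers of
    its cell (exact functionals of the latent field); with ``top_k`` only
    the k most abundant species are kept and covers renormalised,
    emulating incomplete censuses.

    Plots falling in empty cells are re-drawn.  With ``unique_cells`` no
    two plots share a cell; requesting more plots than occupied cells then
    raises.
    """
    if n_plots < 1:
        raise ValueError("n_plots must be >= 1")
    spec = cluster_spec or ClusterSpec()
    rng = np.random.default_rng(seed)
    grid = comm.grid
    x0, y0, x1, y1 = grid.extent
    occupied = comm.occupied
    n_occupied = int(occupied.sum())
    if n_occupied == 0:
        raise RuntimeError("community field has no occupied cells to survey")
    if unique_cells and n_plots > n_occupied:
        raise RuntimeError(
            f"cannot place {n_plots} plots in {n_occupied} occupied cells "
            "without cell reuse"
        )

    if spec.centers is not None:
        centers = np.asarray(spec.centers, dtype=float)
    else:
        centers = np.column_stack(
            [rng.uniform(x0, x1, spec.n_clusters), rng.uniform(y0, y1, spec.n_clusters)]
        )

    xs = np.empty(n_plots)
    ys = np.empty(n_plots)
    used_cells: set[tuple[int, int]] = set()
    placed = 0
    attempts = 0
    max_attempts = 1000 * n_plots
    while placed < n_plots:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError("survey placement failed: too many rejected draws")
        cx, cy = centers[rng.integers(len(centers))]
        px = cx + rng.normal(0.0, spec.dispersion_km)
        py = cy + rng.normal(0.0, spec.dispersion_km)
        if not (x0 <= px < x1 and y0 <= py < y1):
            continue
        col, row, _ = assign_cells(np.array([px]), np.array([py]), grid)
        c, r = int(col[0]), int(row[0])
        if not occupied[r, c]:
            continue
        if unique_cells and (r, c) in used_cells:
            continue
        used_cells.add((r, c))
        xs[placed], ys[placed] = px, py
        placed += 1

    cols, rows, _ = assign_cells(xs, ys, grid)
    records = []
    names = np.asarray(comm.binomials)
    for i in range(n_plots):
        covers = comm.cover[:, rows[i], cols[i]]
        present = covers > 0
        sp, cv = names[present], covers[present]
        if top_k is not None and len(sp) > top_k:
            keep = np.argsort(cv)[::-1][:top_k]
            sp, cv = sp[keep], cv[keep]
            cv = cv / cv.sum()
        for s, c in zip(sp, cv):
            records.append((f"plot_{i:05d}", xs[i], ys[i], s, c))
    return pd.DataFrame(
        records, columns=["plot_id", "x", "y", "species", "relative_cover"]
    )


def sample_occurrences(
    comm: CommunityField,
    n_occ: int,
    effort_surface: np.ndarray | None = None,
    detectability: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Draw opportunistic point records from the latent communities.

    Record cells are drawn proportionally to ``effort_surface`` (uniform
    over occupied cells when None); the species at a record is drawn
    proportionally to ``cover x detectability`` within its cell; the
    point location is uniform within the cell.  Returns columns
    ``record_id, x, y, species``.
    """
    grid = comm.grid
    rng = np.random.default_rng(seed)
    n_species = len(comm.binomials)

    if effort_surface is None:
        effort = np.ones(grid.shape)
    else:
        effort = np.asarray(effort_surface, dtype=float)
        if effort.shape != grid.shape:
            raise ValueError("effort_surface shape does not match grid")
        if np.any(effort < 0):
            raise ValueError("effort must be non-negative")

    det = np.ones(n_species)
    if detectability is not None:
        for i, name in enumerate(comm.binomials):
            det[i] = detectability.get(name, 1.0)
        if np.any((det < 0) | (det > 1)):
            raise ValueError("detectability values must lie in [0, 1]")

    # joint species-in-cell weights; cells where nothing is detectable get 0
    weighted = comm.cover * det[:, None, None]
    cell_weight = weighted.sum(axis=0) * effort
    total = cell_weight.sum()
    if total <= 0:
        raise RuntimeError("all-zero sampling weight: no detectable occurrence possible")

    flat_p = (cell_weight / total).ravel()
    cell_draws = rng.choice(cell_weight.size, size=n_occ, p=flat_p)
    rows, cols = np.unravel_index(cell_draws, grid.shape)

    species_idx = np.empty(n_occ, dtype=np.int64)
    # group draws by cell for vectorised species sampling
    order = np.argsort(cell_draws, kind="stable")
    sorted_cells = cell_draws[order]
    boundaries = np.flatnonzero(np.diff(sorted_cells)) + 1
    for grp in np.split(order, boundaries):
        r, c = rows[grp[0]], cols[grp[0]]
        w = weighted[:, r, c]
        p = w / w.sum()
        species_idx[grp] = rng.choice(n_species, size=len(grp), p=p)

    xs = grid.origin_x + (cols + rng.uniform(0, 1, n_occ)) * grid.cell_edge
    ys = grid.origin_y + (rows + rng.uniform(0, 1, n_occ)) * grid.cell_edge
    names = np.asarray(comm.binomials)
    return pd.DataFrame(
        {
            "record_id": [f"occ_{i:07d}" for i in range(n_occ)],
            "x": xs,
            "y": ys,
            "species": names[species_idx],
        }
    )


def subset_trait_db(
    pool: SpeciesPool,
    coverage_fraction: float = 1.0,
    intraspecific_cv: float = 0.0,
    n_meas_per_species: int = 1,
    seed: int | None = None,
    authority_fraction: float = 0.0,
) -> pd.DataFrame:
    """Build an incomplete, noisy trait-measurement database.

    Exactly ``round(coverage_fraction * n_species)`` species receive
    ``n_meas_per_species`` measurements per trait, multiplicatively noised
    with coefficient of variation ``intraspecific_cv`` around the true
    value; the remaining species have no records at all (the coverage
    gap).  A fraction of emitted names carries an authority suffix
    (e.g. ``"... L."``) to exercise name normalisation.  Returns columns
    ``species, trait, value``.
    """
    if not 0 < coverage_fraction <= 1:
        raise ValueError("coverage_fraction must be in (0, 1]")
    if intraspecific_cv < 0:
        raise ValueError("intraspecific_cv must be >= 0")
    if n_meas_per_species < 1:
        raise ValueError("n_meas_per_species must be >= 1")

    rng = np.random.default_rng(seed)
    n_cov = int(round(coverage_fraction * pool.n_species))
    chosen = rng.choice(pool.n_species, size=n_cov, replace=False)
    suffixes = [" L.", " Mill.", " (L.) Pers.", " DC."]

    records = []
    for idx in chosen:
        name = pool.binomials[idx]
        for trait in pool.trait_names:
            true = pool.traits.iloc[idx][trait]
            noise = rng.normal(0.0, intraspecific_cv, n_meas_per_species)
            values = true * (1.0 + noise)
            for v in values:
                out_name = name
                if authority_fraction > 0 and rng.uniform() < authority_fraction:
                    out_name = name.capitalize() + suffixes[rng.integers(len(suffixes))]
                records.append((out_name, trait, v))
    return pd.DataFrame(records, columns=["species", "trait", "value"])


def true_cwm_surface(
    comm: CommunityField, pool: SpeciesPool, trait_name: str
) -> np.ndarray:
    """The exact community-weighted mean surface — the recovery oracle.

    Per occupied cell, ``sum_s cover_s * true_trait_s`` (covers already
    sum to 1); empty cells are NaN.
    """
    if trait_name not in pool.trait_names:
        raise KeyError(f"trait {trait_name!r} not in pool")
    traits = pool.traits[trait_name].reindex(comm.binomials).to_numpy()
    cwm = np.tensordot(traits, comm.cover, axes=(0, 0))
    return np.where(comm.occupied, cwm, np.nan)
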