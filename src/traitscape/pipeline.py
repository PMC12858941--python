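"""End-to-end pipeline: simulate, match, grid, block, fit, map, score.

The stages run in the order the data flow demands: a synthetic world is
generated (or tabular inputs are loaded), species names are matched
against the trait database and plot CWMs / tagged occurrences derived,
trait values are gridded at each requested resolution, spatial folds are
built per trait from the survey CWM autocorrelation range, one model task
is fitted per (trait, resolution, subset), and each task emits pooled
validation metrics plus — for mapped subsets — a quantized multi-band
raster bundle with COV, DI and AOA layers.  Every output directory
carries the resolved configuration and seed for provenance.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import gridding, matching, synthetic
from .evaluation import compare_variants, compute_metrics
from .grids import EnvironmentStack, GridSpec
from .model import TraitMappingModel
from .modeling import ModelConfig, plan_model_tasks
from .raster_io import TraitMapBundle, write_trait_raster
from .spatial_cv import build_folds, empirical_variogram, fit_spherical, fold_summary

logger = logging.getLogger(__name__)

__all__ = ["WorldConfig", "PipelineConfig", "simulate_world", "run_pipeline"]


@dataclass
class WorldConfig:
    """Synthetic world defaults: a 444 km square plane at 1 km resolution.

    The predictor stack carries five layers of which three drive species
    niches; traits are linked to the first niche axis so the CWM surface
    is a learnable function of the environment.  Sampling intensities are
    chosen so occurrence cells outnumber survey cells roughly five-fold,
    echoing the imbalance between opportunistic records and curated plots.
    """

    extent_km: float = 444.0
    finest_edge_km: float = 1.0
    env_range_km: float = 60.0
    n_layers: int = 5
    n_niche_axes: int = 3
    n_species: int = 36
    n_plots: int = 600
    n_occurrences: int = 50_000
    plot_clusters: int = 8
    plot_dispersion_km: float = 25.0
    effort_bias: float = 1.0  # exponent skewing occurrence effort spatially
    trait_coverage: float = 0.7
    intraspecific_cv: float = 0.15
    n_measurements: int = 4
    authority_fraction: float = 0.3
    traits: tuple[str, ...] = ("leaf_area", "plant_height")
    n_strata: int = 4


@dataclass
class PipelineConfig:
    """Full run configuration."""

    world: WorldConfig = field(default_factory=WorldConfig)
    resolutions_km: tuple[float, ...] = gridding.RESOLUTIONS_KM
    subsets: tuple[str, ...] = ("SCI", "CIT", "COMB")
    K: int = 5
    n_sim: int = 100
    min_occ: int = gridding.MIN_OCC_PER_CELL
    max_occ: int = gridding.MAX_OCC_PER_CELL
    learner_params: dict = field(default_factory=dict)
    prune: bool = False
    map_subsets: tuple[str, ...] = ("SCI", "COMB")
    map_resolutions_km: tuple[float, ...] | None = None  # default: finest only
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        world = WorldConfig(**raw.pop("world", {}))
        cfg = cls(world=world, **raw)
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class World:
    """All synthetic inputs plus their ground truth."""

    grid: GridSpec
    env: EnvironmentStack
    pool: synthetic.SpeciesPool
    comm: synthetic.CommunityField
    surveys: pd.DataFrame
    occurrences: pd.DataFrame
    trait_db: pd.DataFrame


def simulate_world(cfg: WorldConfig, seed: int = 0) -> World:
    """Generate one fully known world from the configuration."""
    n_cells = int(round(cfg.extent_km / cfg.finest_edge_km))
    grid = GridSpec(0.0, 0.0, cfg.finest_edge_km, n_cells, n_cells)
    layer_names = [f"env_{i}" for i in range(cfg.n_layers)]
    env = synthetic.generate_environment(
        grid, layer_names, cfg.env_range_km, noise_sd=1.0, seed=seed,
        n_strata=cfg.n_strata,
    )
    axes = layer_names[: cfg.n_niche_axes]
    trait_specs = {}
    for i, t in enumerate(cfg.traits):
        trait_specs[t] = {
            "dist": "linked",
            "axis": axes[i % len(axes)],
            "intercept": 10.0 + 5.0 * i,
            "slope": 4.0,
            "noise_sd": 1.0,
        }
    niche_spec = {
        a: {"optimum_range": (-2.5, 2.5), "breadth_range": (0.6, 2.0)} for a in axes
    }
    pool = synthetic.generate_species_pool(cfg.n_species, trait_specs, niche_spec, seed=seed + 1)
    comm = synthetic.simulate_communities(env, pool)
    surveys = synthetic.sample_surveys(
        comm,
        cfg.n_plots,
        synthetic.ClusterSpec(cfg.plot_clusters, cfg.plot_dispersion_km),
        seed=seed + 2,
    )
    # spatially biased effort: skewed monotone function of the first layer
    effort = np.exp(cfg.effort_bias * env.layers[layer_names[0]])
    occurrences = synthetic.sample_occurrences(
        comm, cfg.n_occurrences, effort_surface=effort, seed=seed + 3
    )
    trait_db = synthetic.subset_trait_db(
        pool,
        coverage_fraction=cfg.trait_coverage,
        intraspecific_cv=cfg.intraspecific_cv,
        n_meas_per_species=cfg.n_measurements,
        seed=seed + 4,
        authority_fraction=cfg.authority_fraction,
    )
    return World(grid=grid, env=env, pool=pool, comm=comm, surveys=surveys,
                 occurrences=occurrences, trait_db=trait_db)


def write_world(world: World, outdir: Path, cfg: WorldConfig, seed: int) -> None:
    """Persist the tabular inputs as CSV with a JSON provenance sidecar."""
    outdir.mkdir(parents=True, exist_ok=True)
    world.surveys.to_csv(outdir / "surveys.csv", index=False)
    world.occurrences.to_csv(outdir / "occurrences.csv", index=False)
    world.trait_db.to_csv(outdir / "trait_measurements.csv", index=False)
    bundle = TraitMapBundle(
        grid=world.grid,
        bands=dict(world.env.layers),
        metadata={"kind": "environment", "seed": seed},
    )
    write_trait_raster(bundle, outdir / "environment.tif")
    (outdir / "world.json").write_text(
        json.dumps({"config": asdict(cfg), "seed": seed, "grid": world.grid.to_dict()},
                   indent=2, default=str)
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path, overwrite: bool = False) -> dict:
    """Execute every stage and write artifacts; returns the summary dict."""
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not overwrite:
        raise FileExistsError(f"output directory {outdir} is not empty (use overwrite)")
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    seed = config.seed
    (outdir / "config.yaml").write_text(yaml.safe_dump(config.to_dict()))

    def stage(name):
        logger.info("[%7.1fs] stage: %s", time.time() - t0, name)

    stage("simulate")
    world = simulate_world(config.world, seed=seed)
    write_world(world, outdir / "inputs", config.world, seed)

    stage("match")
    means = matching.species_means(world.trait_db)
    match_reports = {}
    plot_cwms = {}
    tagged = {}
    for trait in config.world.traits:
        plot_cwms[trait], rep_s = matching.plot_cwm(world.surveys, means, trait)
        tagged[trait], rep_o = matching.tag_occurrences(world.occurrences, means, trait)
        match_reports[trait] = {"surveys": rep_s.to_dict(), "occurrences": rep_o.to_dict()}
    (outdir / "match_report.json").write_text(json.dumps(match_reports, indent=2))

    tasks = plan_model_tasks(list(config.world.traits), list(config.resolutions_km),
                             list(config.subsets))
    summary: dict = {
        "config_digest": config.digest(),
        "seed": seed,
        "n_model_tasks": len(tasks),
        "metrics": [],
        "uncertainty": [],
    }

    stage("folds")
    folds_per_trait = {}
    for trait in config.world.traits:
        cw = plot_cwms[trait]
        vg = empirical_variogram(cw[["x", "y"]].to_numpy(), cw["cwm"].to_numpy(), seed=seed)
        sph = fit_spherical(vg)
        # hexagons over the union of survey and occurrence points so every
        # labelled cell at any resolution inherits a fold
        pts = np.vstack([cw[["x", "y"]].to_numpy(), tagged[trait][["x", "y"]].to_numpy()])
        vals = np.concatenate([cw["cwm"].to_numpy(), tagged[trait]["value"].to_numpy()])
        folds_per_trait[trait] = build_folds(
            pts, vals, range_km=sph.range_km, K=config.K, n_sim=config.n_sim, seed=seed
        )
        fa = folds_per_trait[trait]
        fold_summary(fa).to_csv(outdir / f"folds_{trait}.csv", index=False)
        (outdir / f"folds_{trait}.json").write_text(
            json.dumps(
                {"range_km": fa.range_km, "K": fa.K, "seed": seed,
                 "balance_score": fa.balance_score,
                 "candidate_scores": fa.candidate_scores.tolist(),
                 "variogram_flagged": sph.flagged},
                indent=2,
            )
        )

    metrics_rows = []
    uncertainty_rows = []
    results_by = {}
    for trait in config.world.traits:
        # one label-side transform per trait, fitted on the survey CWM
        # distribution and reused for every subset and resolution
        params = gridding.fit_transform(plot_cwms[trait]["cwm"].to_numpy(), trait=trait)
        for res in config.resolutions_km:
            grid_r = world.grid.coarsen(res)
            env_r = gridding.aggregate_predictors(world.env, grid_r)
            sub = gridding.subsample_occurrences(
                tagged[trait], grid_r, config.min_occ, config.max_occ, seed=seed
            )
            cwm_grid = gridding.grid_trait_values(plot_cwms[trait], grid_r, "cwm_mean", trait=trait)
            fwm_grid = gridding.grid_trait_values(sub, grid_r, "fwm", trait=trait)
            comb_grid = gridding.merge_comb(cwm_grid, fwm_grid)
            label_grids = {"SCI": cwm_grid, "CIT": fwm_grid, "COMB": comb_grid}
            tables = {}
            for s, lg in label_grids.items():
                try:
                    tables[s] = gridding.build_training_table(lg, env_r, params)
                except RuntimeError as e:
                    logger.warning("(%s, %g km, %s): %s", trait, res, s, e)
                    tables[s] = None

            for subset in config.subsets:
                table = tables.get(subset)
                if table is None or len(table) == 0:
                    logger.warning("skipping empty task (%s, %g km, %s)", trait, res, subset)
                    continue
                mc = ModelConfig(
                    trait=trait, resolution_km=res, subset=subset,
                    learner_params=config.learner_params, prune=config.prune, seed=seed,
                )
                val_table = tables["SCI"] if subset == "CIT" else None
                if subset == "CIT" and (val_table is None or len(val_table) == 0):
                    logger.warning("no survey validation rows for CIT at %g km", res)
                    continue
                stage(f"fit {trait} @ {res:g} km [{subset}]")
                tm = TraitMappingModel(
                    table, env_r.layer_names, params, mc,
                    folds=folds_per_trait[trait], val_table=val_table,
                )
                try:
                    res_obj = tm.fit()
                except RuntimeError as e:
                    logger.warning("task (%s, %g km, %s) failed: %s", trait, res, subset, e)
                    continue
                results_by[(trait, res, subset)] = res_obj
                metrics_rows.append(res_obj.metrics.to_dict())

                map_res = config.map_resolutions_km or (min(config.resolutions_km),)
                if subset in config.map_subsets and res in map_res:
                    stage(f"map {trait} @ {res:g} km [{subset}]")
                    pred = res_obj.predict_map(env_r)
                    up = res_obj.uncertainty(env_r)
                    uncertainty_rows.append(
                        {"trait": trait, "resolution_km": res, "subset": subset,
                         "n_valid_pixels": int(np.isfinite(up.di).sum()),
                         "di_threshold": up.di_threshold,
                         "mean_train_distance": up.mean_train_distance,
                         "percent_inside_aoa": up.percent_inside,
                         "mean_cov": float(np.nanmean(up.cov))}
                    )
                    bundle = TraitMapBundle(
                        grid=grid_r,
                        bands={"prediction": pred, "cov": up.cov, "aoa": up.aoa},
                        metadata={
                            "trait": trait, "resolution_km": res, "subset": subset,
                            "lambda": params.lmbda, "seed": seed,
                            "di_threshold": up.di_threshold,
                            "percent_inside_aoa": up.percent_inside,
                            "config_digest": config.digest(),
                        },
                    )
                    write_trait_raster(
                        bundle, outdir / f"map_{trait}_{res:g}km_{subset}.tif"
                    )

    stage("evaluate")
    metrics_df = pd.DataFrame(metrics_rows)
    metrics_df.to_csv(outdir / "metrics.csv", index=False)
    summary["metrics"] = metrics_rows
    summary["uncertainty"] = uncertainty_rows
    summary["runtime_s"] = round(time.time() - t0, 2)
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary
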