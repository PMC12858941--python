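import numpy as np
import pandas as pd
import pytest
from scipy import stats

from traitscape.grids import GridSpec
from traitscape.spatial_cv import empirical_variogram, fit_spherical
from traitscape.synthetic import (
    ClusterSpec,
    generate_environment,
    generate_species_pool,
    sample_occurrences,
    sample_surveys,
    simulate_communities,
    subset_trait_db,
    true_cwm_surface,
)

from conftest import make_community, make_pool


class TestGenerateEnvironment:
    def test_zero_noise_gives_constant(self):
        g = GridSpec(0, 0, 1.0, 8, 8)
        env = generate_environment(g, ["a"], 10.0, noise_sd=0.0, seed=0, base=3.5)
        assert np.allclose(env["a"], 3.5)

    def test_deterministic_under_seed(self):
        g = GridSpec(0, 0, 1.0, 20, 20)
        e1 = generate_environment(g, ["a", "b"], 10.0, seed=42)
        e2 = generate_environment(g, ["a", "b"], 10.0, seed=42)
        assert np.array_equal(e1["a"], e2["a"]) and np.array_equal(e1["b"], e2["b"])
        e3 = generate_environment(g, ["a", "b"], 10.0, seed=43)
        assert not np.array_equal(e1["a"], e3["a"])

    def test_parameter_errors(self):
        g = GridSpec(0, 0, 1.0, 4, 4)
        with pytest.raises(ValueError):
            generate_environment(g, ["a"], -1.0, seed=0)
        with pytest.raises(ValueError):
            generate_environment(g, [], 5.0, seed=0)

    def test_realized_range_matches_request(self):
        # fit the package's own variogram estimator to the realized field
        g = GridSpec(0, 0, 1.0, 200, 200)
        env = generate_environment(g, ["a"], autocorr_range_km=30.0, seed=0)
        rng = np.random.default_rng(0)
        idx = rng.choice(200 * 200, 4000, replace=False)
        r, c = np.unravel_index(idx, (200, 200))
        pts = np.column_stack([c + 0.5, r + 0.5]).astype(float)
        vg = empirical_variogram(pts, env["a"][r, c], n_bins=15, max_lag=80, seed=0)
        fit = fit_spherical(vg)
        assert 0.7 * 30 <= fit.range_km <= 1.3 * 30

    def test_strata_layer(self):
        g = GridSpec(0, 0, 1.0, 30, 30)
        env = generate_environment(g, ["a"], 10.0, seed=1, n_strata=4)
        assert set(np.unique(env.strata)) == {0, 1, 2, 3}


class TestGenerateSpeciesPool:
    NICHE = {"env_0": {"optimum_range": (-1, 1), "breadth_range": (0.5, 1.5)}}

    def test_degenerate_trait_distribution(self):
        pool = generate_species_pool(
            2, {"t": {"dist": "constant", "value": 7.0}}, self.NICHE, seed=0
        )
        assert (pool.traits["t"] == 7.0).all()

    def test_lognormal_moments(self):
        pool = generate_species_pool(
            1000, {"t": {"dist": "lognormal", "mu": 0.0, "sigma": 1.0}}, self.NICHE, seed=0
        )
        # log-mean tolerance sigma/sqrt(n) ~ 0.032; spec allows 0.1
        assert abs(np.log(pool.traits["t"]).mean()) < 0.1

    def test_binomials_unique_and_lowercase(self):
        pool = generate_species_pool(
            200, {"t": {"dist": "normal", "mean": 0, "sd": 1}}, self.NICHE, seed=0
        )
        assert len(set(pool.binomials)) == 200
        assert all(n == n.lower() and len(n.split()) == 2 for n in pool.binomials)

    def test_deterministic_and_duplicate_errors(self):
        spec = {"t": {"dist": "normal", "mean": 0, "sd": 1}}
        p1 = generate_species_pool(50, spec, self.NICHE, seed=5)
        p2 = generate_species_pool(50, spec, self.NICHE, seed=5)
        pd.testing.assert_frame_equal(p1.traits, p2.traits)
        with pytest.raises(ValueError):
            generate_species_pool(50, [("t", spec["t"]), ("t", spec["t"])], self.NICHE, seed=0)
        with pytest.raises(ValueError):
            generate_species_pool(1, spec, self.NICHE, seed=0)


class TestSimulateCommunities:
    def test_identical_niches_give_equal_covers(self):
        g = GridSpec(0, 0, 1.0, 5, 5)
        env = generate_environment(g, ["env_0"], 5.0, seed=0)
        pool = make_pool({"t": [1.0, 2.0, 3.0]}, optima={"env_0": [0.0] * 3},
                         breadths={"env_0": [1.0] * 3})
        comm = simulate_communities(env, pool, absence_floor=0.0)
        occ = comm.occupied
        assert np.allclose(comm.cover[:, occ], 1 / 3)

    def test_monotone_niche_response(self):
        g = GridSpec(0, 0, 1.0, 1, 1)
        env_arr = np.array([[0.0]])
        from traitscape.grids import EnvironmentStack

        env = EnvironmentStack(grid=g, layers={"env_0": env_arr})
        pool = make_pool({"t": [1.0, 2.0]}, optima={"env_0": [0.0, 10.0]},
                         breadths={"env_0": [2.0, 2.0]})
        comm = simulate_communities(env, pool)
        assert comm.cover[0, 0, 0] > comm.cover[1, 0, 0]

    def test_renormalization_hand_oracle(self):
        # responses (0.2, 0.6) must renormalize to covers (0.25, 0.75):
        # with unit breadth, response exp(-(e-o)^2/2) = 0.2 / 0.6 at
        # offsets sqrt(-2 ln r)
        g = GridSpec(0, 0, 1.0, 1, 1)
        from traitscape.grids import EnvironmentStack

        env = EnvironmentStack(grid=g, layers={"env_0": np.array([[0.0]])})
        o1 = np.sqrt(-2 * np.log(0.2))
        o2 = np.sqrt(-2 * np.log(0.6))
        pool = make_pool({"t": [1.0, 2.0]}, optima={"env_0": [o1, o2]},
                         breadths={"env_0": [1.0, 1.0]})
        comm = simulate_communities(env, pool)
        assert np.allclose(comm.cover[:, 0, 0], [0.25, 0.75], atol=1e-12)

    def test_cover_conservation(self):
        g = GridSpec(0, 0, 1.0, 20, 20)
        env = generate_environment(g, ["env_0", "env_1"], 8.0, seed=3)
        niche = {a: {"optimum_range": (-2, 2), "breadth_range": (0.5, 1.5)}
                 for a in ("env_0", "env_1")}
        pool = generate_species_pool(15, {"t": {"dist": "normal", "mean": 5, "sd": 1}},
                                     niche, seed=3)
        comm = simulate_communities(env, pool)
        sums = comm.cover.sum(axis=0)
        occ = comm.occupied
        assert np.all(np.abs(sums[occ] - 1.0) < 1e-9)
        assert np.all(sums[~occ] == 0.0)

    def test_missing_axis_errors(self):
        g = GridSpec(0, 0, 1.0, 2, 2)
        env = generate_environment(g, ["other"], 5.0, seed=0)
        pool = make_pool({"t": [1.0, 2.0]})
        with pytest.raises(KeyError):
            simulate_communities(env, pool)


class TestSampleSurveys:
    def test_records_exact_covers(self, grid4, two_species_world):
        _, comm = two_species_world
        sv = sample_surveys(comm, 5, seed=0)
        for _, grp in sv.groupby("plot_id"):
            got = dict(zip(grp["species"], grp["relative_cover"]))
            assert got == {"genus00 species00": 0.6, "genus01 species01": 0.4}

    def test_cover_sums_to_one(self, two_species_world):
        _, comm = two_species_world
        sv = sample_surveys(comm, 10, seed=1, top_k=1)
        sums = sv.groupby("plot_id")["relative_cover"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_tight_cluster_confines_plots(self):
        g = GridSpec(0, 0, 1.0, 50, 50)
        cover = np.full((2, 50, 50), 0.5)
        comm = make_community(g, cover)
        spec = ClusterSpec(n_clusters=1, dispersion_km=1.0, centers=np.array([[25.0, 25.0]]))
        sv = sample_surveys(comm, 40, cluster_spec=spec, seed=2)
        plots = sv.drop_duplicates("plot_id")
        d = np.hypot(plots["x"] - 25.0, plots["y"] - 25.0)
        # 99.7% of |N(0,1)| below 3; allow the extreme quantile some room
        assert np.quantile(d, 0.95) < 3.0

    def test_unique_cells_exhaustion_errors(self, two_species_world):
        _, comm = two_species_world  # 16 occupied cells
        with pytest.raises(RuntimeError):
            sample_surveys(comm, 17, seed=0, unique_cells=True)


class TestSampleOccurrences:
    def test_zero_effort_region_gets_no_records(self, two_species_world):
        _, comm = two_species_world
        effort = np.ones((4, 4))
        effort[:, :2] = 0.0
        occ = sample_occurrences(comm, 500, effort_surface=effort, seed=0)
        assert (occ["x"] >= 2.0).all()

    def test_species_frequency_matches_cover(self):
        g = GridSpec(0, 0, 1.0, 1, 1)
        comm = make_community(g, np.array([[[0.5]], [[0.5]]]))
        occ = sample_occurrences(comm, 10_000, seed=0)
        f = (occ["species"] == comm.binomials[0]).mean()
        assert abs(f - 0.5) < 0.02

    def test_zero_detectability_excludes_species(self, two_species_world):
        _, comm = two_species_world
        occ = sample_occurrences(
            comm, 200, detectability={comm.binomials[1]: 0.0}, seed=0
        )
        assert (occ["species"] == comm.binomials[0]).all()

    def test_frequency_goodness_of_fit(self):
        # chi-square GOF against cover x detectability in one cell
        g = GridSpec(0, 0, 1.0, 1, 1)
        covers = np.array([0.5, 0.3, 0.2])
        comm = make_community(g, covers.reshape(3, 1, 1))
        det = {f"genus{i:02d} species{i:02d}": d for i, d in enumerate([1.0, 0.5, 1.0])}
        expected_p = covers * np.array([1.0, 0.5, 1.0])
        expected_p /= expected_p.sum()
        occ = sample_occurrences(comm, 10_000, detectability=det, seed=4)
        counts = occ["species"].value_counts().reindex(comm.binomials).fillna(0)
        res = stats.chisquare(counts, expected_p * 10_000)
        assert res.pvalue > 0.01

    def test_reproducible_and_seed_sensitive(self, two_species_world):
        _, comm = two_species_world
        a = sample_occurrences(comm, 100, seed=9)
        b = sample_occurrences(comm, 100, seed=9)
        pd.testing.assert_frame_equal(a, b)
        c = sample_occurrences(comm, 100, seed=10)
        assert not a.equals(c)

    def test_all_zero_effort_errors(self, two_species_world):
        _, comm = two_species_world
        with pytest.raises(RuntimeError):
            sample_occurrences(comm, 10, effort_surface=np.zeros((4, 4)), seed=0)


class TestSubsetTraitDb:
    def test_noise_free_measurements_equal_truth(self):
        pool = make_pool({"t": [3.0, 8.0]})
        db = subset_trait_db(pool, 1.0, 0.0, 3, seed=0)
        truth = pool.traits["t"]
        for sp, grp in db.groupby("species"):
            assert np.allclose(grp["value"], truth[sp])

    def test_exact_coverage_subset_size(self):
        niche = {"env_0": {"optimum_range": (-1, 1), "breadth_range": (0.5, 1.5)}}
        pool = generate_species_pool(100, {"t": {"dist": "normal", "mean": 5, "sd": 1}},
                                     niche, seed=0)
        db = subset_trait_db(pool, 0.5, 0.0, 1, seed=0)
        assert db["species"].nunique() == 50

    def test_intraspecific_cv_recovered(self):
        pool = make_pool({"t": [10.0, 20.0]})
        db = subset_trait_db(pool, 1.0, 0.1, 200, seed=1)
        for _, grp in db.groupby("species"):
            cv = grp["value"].std() / grp["value"].mean()
            assert abs(cv - 0.1) < 0.03

    def test_authority_noise_still_normalizable(self):
        from traitscape.matching import normalize_names

        pool = make_pool({"t": [1.0, 2.0]})
        db = subset_trait_db(pool, 1.0, 0.0, 5, seed=2, authority_fraction=1.0)
        assert set(normalize_names(db["species"])) <= set(pool.binomials)


class TestTrueCwmSurface:
    def test_symmetric_mean(self, grid4):
        pool = make_pool({"t": [10.0, 30.0]})
        comm = make_community(grid4, np.full((2, 4, 4), 0.5), pool.binomials)
        assert np.allclose(true_cwm_surface(comm, pool, "t"), 20.0)

    def test_single_species_identity(self, grid4):
        pool = make_pool({"t": [7.0, 9.0]})
        cover = np.zeros((2, 4, 4))
        cover[0] = 1.0
        comm = make_community(grid4, cover, pool.binomials)
        assert np.allclose(true_cwm_surface(comm, pool, "t"), 7.0)

    def test_weighted_mean_hand_oracle(self, two_species_world):
        pool, comm = two_species_world
        cwm = true_cwm_surface(comm, pool, "t")
        assert np.allclose(cwm, 0.6 * 5 + 0.4 * 20)  # 11.0

    def test_convexity_bounds(self):
        g = GridSpec(0, 0, 1.0, 15, 15)
        env = generate_environment(g, ["env_0"], 6.0, seed=2)
        niche = {"env_0": {"optimum_range": (-2, 2), "breadth_range": (0.5, 2.0)}}
        pool = generate_species_pool(10, {"t": {"dist": "lognormal", "mu": 1, "sigma": 0.5}},
                                     niche, seed=2)
        comm = simulate_communities(env, pool)
        cwm = true_cwm_surface(comm, pool, "t")
        finite = np.isfinite(cwm)
        assert cwm[finite].min() >= pool.traits["t"].min() - 1e-12
        assert cwm[finite].max() <= pool.traits["t"].max() + 1e-12
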