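import numpy as np
import pandas as pd
import pytest

from traitscape.gridding import (
    SOURCE_OCCURRENCE,
    SOURCE_SURVEY,
    aggregate_predictors,
    apply_transform,
    build_training_table,
    fit_transform,
    grid_trait_values,
    invert_transform,
    merge_comb,
    subsample_occurrences,
)
from traitscape.grids import EnvironmentStack, GridSpec


def tagged_rows(cell_counts: dict[tuple[int, int], int], grid: GridSpec, value=1.0):
    """Occurrence rows placed at cell centers, n per cell."""
    rows = []
    i = 0
    for (col, row), n in cell_counts.items():
        for _ in range(n):
            rows.append(
                (f"r{i}", grid.origin_x + (col + 0.5) * grid.cell_edge,
                 grid.origin_y + (row + 0.5) * grid.cell_edge, "t", value)
            )
            i += 1
    return pd.DataFrame(rows, columns=["record_id", "x", "y", "trait", "value"])


class TestSubsampleOccurrences:
    def test_min_max_rule(self):
        g = GridSpec(0, 0, 1.0, 3, 1)
        rows = tagged_rows({(0, 0): 7, (1, 0): 620, (2, 0): 250}, g)
        out = subsample_occurrences(rows, g, min_occ=10, max_occ=500, seed=0)
        counts = out.groupby(np.floor(out["x"]).astype(int)).size()
        assert 0 not in counts.index  # 7 < 10: cell dropped entirely
        assert counts[1] == 500  # thinned to exactly max
        assert counts[2] == 250  # within bounds: untouched

    def test_within_bounds_passthrough_keeps_rows(self):
        g = GridSpec(0, 0, 1.0, 1, 1)
        rows = tagged_rows({(0, 0): 250}, g)
        out = subsample_occurrences(rows, g, seed=1)
        assert sorted(out["record_id"]) == sorted(rows["record_id"])

    def test_reproducible_under_seed(self):
        g = GridSpec(0, 0, 1.0, 1, 1)
        rows = tagged_rows({(0, 0): 600}, g)
        a = subsample_occurrences(rows, g, seed=7)
        b = subsample_occurrences(rows, g, seed=7)
        pd.testing.assert_frame_equal(a, b)

    def test_all_counts_within_bounds_property(self):
        rng = np.random.default_rng(0)
        g = GridSpec(0, 0, 1.0, 5, 5)
        counts = {(c, r): int(rng.integers(1, 800)) for c in range(5) for r in range(5)}
        out = subsample_occurrences(tagged_rows(counts, g), g, seed=0)
        per_cell = out.groupby(
            [np.floor(out["x"]).astype(int), np.floor(out["y"]).astype(int)]
        ).size()
        assert per_cell.between(10, 500).all()

    def test_threshold_validation(self):
        g = GridSpec(0, 0, 1.0, 1, 1)
        with pytest.raises(ValueError):
            subsample_occurrences(tagged_rows({(0, 0): 5}, g), g, min_occ=0)


class TestGridTraitValues:
    def test_cell_mean_oracle(self):
        g = GridSpec(0, 0, 1.0, 1, 1)
        rows = pd.DataFrame(
            {"record_id": list("abc"), "x": [0.2, 0.5, 0.9], "y": [0.5] * 3,
             "trait": "t", "value": [2.0, 4.0, 6.0]}
        )
        tg = grid_trait_values(rows, g, "fwm")
        assert tg.values[0, 0] == pytest.approx(4.0)
        assert tg.counts[0, 0] == 3
        assert tg.source[0, 0] == SOURCE_OCCURRENCE

    def test_constant_field(self):
        g = GridSpec(0, 0, 1.0, 4, 4)
        rows = tagged_rows({(c, r): 3 for c in range(4) for r in range(2)}, g, value=5.5)
        tg = grid_trait_values(rows, g, "fwm")
        assert np.allclose(tg.values[tg.occupied], 5.5)
        assert tg.n_cells == 8

    def test_survey_mode_uses_cwm_column(self):
        g = GridSpec(0, 0, 1.0, 2, 1)
        rows = pd.DataFrame(
            {"plot_id": ["p1", "p2"], "x": [0.5, 0.6], "y": [0.5, 0.5],
             "trait": "t", "cwm": [3.0, 5.0]}
        )
        tg = grid_trait_values(rows, g, "cwm_mean")
        assert tg.values[0, 0] == pytest.approx(4.0)
        assert tg.source[0, 0] == SOURCE_SURVEY

    def test_empty_input_empty_grid(self):
        g = GridSpec(0, 0, 1.0, 2, 2)
        tg = grid_trait_values(pd.DataFrame(columns=["x", "y", "value"]), g, "fwm", trait="t")
        assert tg.n_cells == 0


class TestMergeComb:
    def make(self, grid, cells, source, value):
        values = np.full(grid.shape, np.nan)
        counts = np.zeros(grid.shape, dtype=np.int64)
        src = np.zeros(grid.shape, dtype=np.int8)
        for r, c in cells:
            values[r, c], counts[r, c], src[r, c] = value, 1, source
        from traitscape.gridding import TraitGrid

        return TraitGrid(grid=grid, trait="t", values=values, counts=counts, source=src)

    def test_survey_precedence(self):
        g = GridSpec(0, 0, 1.0, 2, 2)
        cwm = self.make(g, [(0, 0)], SOURCE_SURVEY, 3.0)
        fwm = self.make(g, [(0, 0), (1, 1)], SOURCE_OCCURRENCE, 9.0)
        merged = merge_comb(cwm, fwm)
        assert merged.values[0, 0] == 3.0 and merged.source[0, 0] == SOURCE_SURVEY
        assert merged.values[1, 1] == 9.0 and merged.source[1, 1] == SOURCE_OCCURRENCE

    def test_union_occupancy(self):
        g = GridSpec(0, 0, 1.0, 3, 3)
        cwm = self.make(g, [(0, 0), (1, 1)], SOURCE_SURVEY, 1.0)
        fwm = self.make(g, [(1, 1), (2, 2)], SOURCE_OCCURRENCE, 2.0)
        merged = merge_comb(cwm, fwm)
        assert np.array_equal(merged.occupied, cwm.occupied | fwm.occupied)

    def test_grid_mismatch_errors(self):
        a = self.make(GridSpec(0, 0, 1.0, 2, 2), [], SOURCE_SURVEY, 0.0)
        b = self.make(GridSpec(0, 0, 2.0, 2, 2), [], SOURCE_OCCURRENCE, 0.0)
        with pytest.raises(ValueError):
            merge_comb(a, b)


class TestAggregatePredictors:
    def test_constant_layer_preserved(self):
        g = GridSpec(0, 0, 1.0, 4, 4)
        env = EnvironmentStack(grid=g, layers={"a": np.full((4, 4), 2.0)})
        out = aggregate_predictors(env, g.coarsen(2.0))
        assert np.allclose(out["a"], 2.0)

    def test_block_mean_oracle(self):
        g = GridSpec(0, 0, 1.0, 2, 2)
        env = EnvironmentStack(grid=g, layers={"a": np.array([[1.0, 2.0], [3.0, 4.0]])})
        out = aggregate_predictors(env, g.coarsen(2.0))
        assert out["a"][0, 0] == pytest.approx(2.5)

    def test_nodata_renormalized_mean(self):
        g = GridSpec(0, 0, 1.0, 2, 2)
        env = EnvironmentStack(
            grid=g, layers={"a": np.array([[1.0, 2.0], [np.nan, np.nan]])}
        )
        out = aggregate_predictors(env, g.coarsen(2.0))
        assert out["a"][0, 0] == pytest.approx(1.5)

    def test_global_mean_conserved_without_nodata(self):
        rng = np.random.default_rng(0)
        g = GridSpec(0, 0, 1.0, 12, 12)
        env = EnvironmentStack(grid=g, layers={"a": rng.normal(size=(12, 12))})
        out = aggregate_predictors(env, g.coarsen(3.0))
        assert out["a"].mean() == pytest.approx(env["a"].mean(), abs=1e-9)

    def test_upsampling_rejected(self):
        g = GridSpec(0, 0, 2.0, 2, 2)
        env = EnvironmentStack(grid=g, layers={"a": np.zeros((2, 2))})
        with pytest.raises(ValueError):
            aggregate_predictors(env, GridSpec(0, 0, 1.0, 4, 4))


class TestYeoJohnson:
    def test_zero_fixed_point_any_lambda(self):
        for lam in (-1.0, 0.0, 0.5, 1.0, 2.0, 3.0):
            from traitscape.gridding import TransformParams

            p = TransformParams(trait="t", lmbda=lam)
            assert apply_transform(np.array([0.0]), p)[0] == pytest.approx(0.0)

    def test_lambda_one_identity_on_nonnegative(self):
        from traitscape.gridding import TransformParams

        p = TransformParams(trait="t", lmbda=1.0)
        x = np.linspace(0, 10, 25)
        assert np.allclose(apply_transform(x, p), x)

    def test_round_trip_mixed_signs(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 5, 500)  # mixed-sign
        params = fit_transform(x, standardize=True)
        back = invert_transform(apply_transform(x, params), params)
        assert np.max(np.abs(back - x)) < 1e-8

    def test_fitted_lambda_symmetrizes_lognormal(self):
        rng = np.random.default_rng(1)
        x = rng.lognormal(0, 1, 2000)
        params = fit_transform(x)
        from scipy.stats import skew

        assert abs(skew(apply_transform(x, params))) < abs(skew(x))


class TestBuildTrainingTable:
    def setup(self):
        self.g = GridSpec(0, 0, 1.0, 1, 3)
        # 10 predictors; per-cell completeness 50%, 60%, 100%
        layers = {}
        for i in range(10):
            arr = np.full((3, 1), float(i))
            if i >= 5:
                arr[0, 0] = np.nan  # cell (row 0): 5/10 present
            if i >= 6:
                arr[1, 0] = np.nan  # cell (row 1): 6/10 present
            layers[f"p{i}"] = arr
        self.env = EnvironmentStack(grid=self.g, layers=layers)
        from traitscape.gridding import TraitGrid

        values = np.array([[2.0], [3.0], [4.0]])
        self.label = TraitGrid(
            grid=self.g, trait="t", values=values,
            counts=np.ones((3, 1), dtype=np.int64),
            source=np.full((3, 1), SOURCE_SURVEY, dtype=np.int8),
        )
        self.params = fit_transform(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))

    def test_completeness_boundary(self):
        self.setup()
        table = build_training_table(self.label, self.env, self.params)
        # 50% row dropped; 60% row kept (only strictly-fewer excluded); 100% kept
        assert set(table["row"]) == {1, 2}

    def test_label_transformed(self):
        self.setup()
        table = build_training_table(self.label, self.env, self.params)
        full = table[table["row"] == 2]
        assert full["label"].iloc[0] == pytest.approx(
            apply_transform(np.array([4.0]), self.params)[0]
        )
        assert full["label_raw"].iloc[0] == 4.0

    def test_no_survivors_errors(self):
        self.setup()
        with pytest.raises(RuntimeError):
            build_training_table(self.label, self.env, self.params, min_predictor_frac=1.01)
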