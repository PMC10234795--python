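"""Grid enumeration, outcome prediction over the grid, and the optimal
time-use zone."""

import math

import numpy as np
import pandas as pd
import pytest

from move24.coda import (CompositionMentalHealthModel, close,
                         geometric_mean_composition, pivot_ilr, replace_zeros)
from move24.goldilocks import (GridSpec, enumerate_grid, goldilocks_search,
                               optimal_zone, predict_grid, radar_data,
                               truncation_ranges)

PARTS = ("sleep", "st", "lpa", "mpa", "vpa")


class TestTruncationRanges:
    def test_three_sd_arithmetic(self):
        rng = np.random.default_rng(0)
        comps = rng.normal([480, 520, 300, 100, 40], [40, 30, 20, 10, 5],
                           size=(5000, 5))
        spec = truncation_ranges(comps, k=3, clip_to_observed=False)
        lo, hi = spec.ranges["sleep"]
        assert lo == pytest.approx(480 - 3 * 40, abs=15)
        assert hi == pytest.approx(480 + 3 * 40, abs=15)

    def test_k_zero_collapses_to_mean(self):
        comps = np.array([[480, 520, 300, 100, 40.0],
                          [500, 500, 300, 100, 40.0]])
        spec = truncation_ranges(comps, k=0)
        lo, hi = spec.ranges["sleep"]
        assert lo == hi == 490

    def test_covers_observed_non_outliers(self, regression_cohort):
        gt = regression_cohort.ground_truth["participants"]
        comps = gt[[f"true_{b}" for b in PARTS]].to_numpy()
        spec = truncation_ranges(comps, k=3)
        inside = np.ones(len(comps), dtype=bool)
        for j, p in enumerate(PARTS):
            lo, hi = spec.ranges[p]
            inside &= (comps[:, j] >= lo - 10) & (comps[:, j] <= hi + 10)
        assert inside.mean() > 0.97

    def test_degenerate_sd_rejected(self):
        comps = np.tile([480, 520, 300, 100, 40.0], (4, 1))
        with pytest.raises(ValueError):
            truncation_ranges(comps, k=3)


class TestEnumerateGrid:
    def test_toy_three_part_matches_brute_force(self):
        spec = GridSpec(ranges={"a": (10, 40), "b": (10, 40), "c": (10, 40)},
                        step=10, total=60, parts=("a", "b", "c"))
        grid = enumerate_grid(spec)
        brute = [(a, b, c)
                 for a in range(10, 41, 10)
                 for b in range(10, 41, 10)
                 for c in range(10, 41, 10) if a + b + c == 60]
        assert sorted(map(tuple, grid.tolist())) == sorted(brute)

    def test_rows_sum_to_1440(self):
        spec = GridSpec(ranges={"sleep": (420, 600), "st": (420, 600),
                                "lpa": (240, 360), "mpa": (40, 100),
                                "vpa": (0, 40)}, step=10)
        grid = enumerate_grid(spec)
        assert (grid.sum(axis=1) == 1440).all()
        assert len(np.unique(grid, axis=0)) == len(grid)

    def test_lexicographic_order(self):
        spec = GridSpec(ranges={"a": (0, 60), "b": (0, 60), "c": (0, 60)},
                        step=10, total=60, parts=("a", "b", "c"))
        grid = enumerate_grid(spec)
        assert sorted(map(tuple, grid.tolist())) == list(map(tuple, grid.tolist()))

    def test_infeasible_ranges_rejected(self):
        spec = GridSpec(ranges={"a": (0, 10), "b": (0, 10), "c": (0, 10)},
                        step=10, total=60, parts=("a", "b", "c"))
        with pytest.raises(ValueError):
            enumerate_grid(spec)

    def test_five_part_count_matches_bounded_oracle(self):
        spec = GridSpec(ranges={"sleep": (450, 550), "st": (450, 550),
                                "lpa": (250, 350), "mpa": (40, 80),
                                "vpa": (10, 40)}, step=10)
        grid = enumerate_grid(spec)
        count = sum(
            1
            for a in range(45, 56) for b in range(45, 56)
            for c in range(25, 36) for d in range(4, 9)
            if 1 <= 144 - a - b - c - d <= 4)
        assert len(grid) == count


class TestPredictGrid:
    def _fitted(self, seed=0, effect=-4.0):
        rng = np.random.default_rng(seed)
        comps = close(np.exp(rng.normal(np.log([500, 520, 300, 80, 20]), 0.2,
                                        size=(250, 5))))
        df = pd.DataFrame(comps, columns=PARTS)
        df["bmiz"] = rng.normal(0, 1, 250)
        z1 = pivot_ilr(comps, "sleep")[:, 0]
        df["y"] = 12 + effect * z1 + 0.5 * df["bmiz"] + rng.normal(0, 1, 250)
        model = CompositionMentalHealthModel.from_dataframe(
            df, "y", covariates=["bmiz"], school_col=None)
        return model.fit(method="ols", stratify_on_sex=False), comps

    def test_zero_ilr_coefficients_constant_predictions(self):
        res, _ = self._fitted()
        params = res.params_by_pivot["sleep"].copy()
        for j in range(4):
            params[f"z{j + 1}"] = 0.0
        res.params_by_pivot["sleep"] = params
        grid = enumerate_grid(GridSpec(ranges={
            "sleep": (450, 550), "st": (450, 550), "lpa": (250, 350),
            "mpa": (40, 80), "vpa": (10, 40)}, step=10))
        pred = predict_grid(grid, res)
        assert np.ptp(pred) == pytest.approx(0.0, abs=1e-10)

    def test_monotone_in_sleep_ratio(self):
        res, _ = self._fitted(effect=-4.0)
        # increase sleep holding the other behaviours' ratios fixed
        rest = np.array([520.0, 300.0, 80.0, 20.0])
        comps = np.array([np.concatenate([[s], rest * (1440 - s) / rest.sum()])
                          for s in (420, 480, 540, 600)])
        pred = predict_grid(comps, res)
        assert np.all(np.diff(pred) < 0)

    def test_matches_manual_ilr_oracle(self):
        res, _ = self._fitted(seed=3)
        grid = np.array([[480, 520, 330, 80, 30], [520, 480, 330, 80, 30.0],
                         [500, 500, 330, 80, 30.0]])
        params = res.params_by_pivot["sleep"]
        z = pivot_ilr(grid, "sleep")
        manual = (params["const"] + z @ params[[f"z{j+1}" for j in range(4)]].to_numpy()
                  + params["bmiz"] * res.covariate_reference["bmiz"])
        np.testing.assert_allclose(predict_grid(grid, res), manual)

    def test_zero_vpa_routed_through_replacement(self):
        res, _ = self._fitted()
        grid = np.array([[500, 520, 330, 90, 0.0]])
        pred = predict_grid(grid, res)
        assert np.isfinite(pred).all()


class TestOptimalZone:
    def test_constant_predictions_zone_is_whole_grid(self):
        grid = enumerate_grid(GridSpec(ranges={
            "sleep": (450, 550), "st": (450, 550), "lpa": (250, 350),
            "mpa": (40, 80), "vpa": (10, 40)}, step=10))
        res = optimal_zone(grid, np.zeros(len(grid)), fraction=0.05)
        assert res.zone_size == res.grid_size
        np.testing.assert_allclose(
            res.optimal_composition,
            geometric_mean_composition(grid.astype(float)))

    def test_zone_size_at_least_ceil_fraction(self):
        rng = np.random.default_rng(1)
        grid = enumerate_grid(GridSpec(ranges={
            "sleep": (450, 550), "st": (450, 550), "lpa": (250, 350),
            "mpa": (40, 80), "vpa": (10, 40)}, step=10))
        pred = rng.normal(size=len(grid))
        res = optimal_zone(grid, pred, fraction=0.05)
        assert res.zone_size >= math.ceil(0.05 * res.grid_size)

    def test_direction_flip_selects_other_tail(self):
        grid = enumerate_grid(GridSpec(ranges={
            "sleep": (450, 550), "st": (450, 550), "lpa": (250, 350),
            "mpa": (40, 80), "vpa": (10, 40)}, step=10))
        pred = np.arange(len(grid), dtype=float)
        low = optimal_zone(grid, pred, fraction=0.05, direction="lower")
        high = optimal_zone(grid, pred, fraction=0.05, direction="higher")
        assert not np.any(low.zone_mask & high.zone_mask)
        assert pred[low.zone_mask].max() < pred[high.zone_mask].min()

    def test_zone_mean_invariant_to_grid_order(self):
        rng = np.random.default_rng(2)
        grid = enumerate_grid(GridSpec(ranges={
            "sleep": (450, 550), "st": (450, 550), "lpa": (250, 350),
            "mpa": (40, 80), "vpa": (10, 40)}, step=10))
        pred = rng.normal(size=len(grid))
        perm = rng.permutation(len(grid))
        a = optimal_zone(grid, pred, fraction=0.05)
        b = optimal_zone(grid[perm], pred[perm], fraction=0.05)
        np.testing.assert_allclose(a.optimal_composition,
                                   b.optimal_composition)

    def test_planted_interior_optimum_recovered_within_one_step(self):
        spec = GridSpec(ranges={"sleep": (420, 620), "st": (380, 620),
                                "lpa": (220, 420), "mpa": (30, 110),
                                "vpa": (10, 40)}, step=10)
        grid = enumerate_grid(spec)
        target = np.array([520.0, 500.0, 330.0, 70.0, 20.0])
        z = pivot_ilr(grid.astype(float), "sleep")
        zt = pivot_ilr(target, "sleep")
        pred = ((z - zt) ** 2).sum(axis=1)
        res = optimal_zone(grid, pred, fraction=0.05, spec=spec)
        assert np.abs(res.optimal_composition - target).max() <= 10.0

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            optimal_zone(np.zeros((0, 5)), np.zeros(0))


class TestRadarData:
    def test_identical_traces_and_mvpa_sum(self):
        comp = close([520, 500, 330, 70, 20])
        table = radar_data(comp, comp)
        np.testing.assert_allclose(table["optimal_min"],
                                   table["sample_mean_min"])
        assert table.loc["mvpa", "optimal_min"] == pytest.approx(90.0)

    def test_guideline_markers(self):
        table = radar_data(close([520, 500, 330, 70, 20]),
                           close([500, 520, 330, 70, 20]))
        assert table.loc["sleep", "guideline_min"] == 540.0
        assert table.loc["mvpa", "guideline_min"] == 60.0


class TestEndToEnd:
    def test_goldilocks_search_runs(self, regression_cohort):
        gt = regression_cohort.ground_truth["participants"]
        comps = gt[[f"true_{b}" for b in PARTS]].to_numpy()
        df = pd.DataFrame(replace_zeros(comps), columns=PARTS)
        df["y"] = gt["sdq_total"].to_numpy(dtype=float)
        model = CompositionMentalHealthModel.from_dataframe(df, "y",
                                                            school_col=None)
        res = model.fit(method="ols", stratify_on_sex=False)
        gl = goldilocks_search(comps, res, outcome="sdq_total")
        assert gl.zone_size >= math.ceil(0.05 * gl.grid_size)
        assert gl.optimal_composition.sum() == pytest.approx(1440.0)
        # lower SDQ planted with more sleep: optimum sleeps more than mean
        assert gl.optimal_composition[0] > gl.sample_mean_composition[0]
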