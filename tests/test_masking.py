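"""Stage 1: variance seeding, ROI edits, threshold fitting, classification."""

import numpy as np
import pytest
from scipy.stats import norm

from vtshape import (
    ImageRun,
    RegionOfInterest,
    classify_run,
    compute_variance_map,
    edit_roi,
    fit_threshold,
    seed_roi,
)
from vtshape.errors import DegenerateError, ValidationError
from vtshape.types import VarianceMap


class TestVarianceMap:
    def test_constant_stack_all_zero(self):
        run = ImageRun(np.full((5, 8, 8), 3.0))
        assert not compute_variance_map(run).values.any()

    def test_alternating_pixel_closed_form(self):
        """A 0,1,0,1 time series has population variance exactly 0.25."""
        stack = np.zeros((4, 2, 2))
        stack[1, 0, 0] = stack[3, 0, 0] = 1.0
        vmap = compute_variance_map(ImageRun(stack))
        assert vmap.values[0, 0] == pytest.approx(0.25)
        assert vmap.values[1, 1] == 0.0

    def test_matches_two_pass_oracle(self, rng):
        stack = rng.uniform(0, 50, (7, 10, 10))
        vmap = compute_variance_map(ImageRun(stack))
        mean = stack.sum(axis=0) / 7
        oracle = ((stack - mean) ** 2).sum(axis=0) / 7
        np.testing.assert_allclose(vmap.values, oracle, atol=1e-10)

    def test_single_frame_rejected(self):
        with pytest.raises(ValidationError):
            compute_variance_map(ImageRun(np.zeros((1, 4, 4))))


class TestSeedRoi:
    def test_sparse_map_quantile_selects_nonzero(self, rng):
        """10 nonzero pixels of 100 at quantile 0.90: the ROI is exactly those 10."""
        values = np.zeros(100)
        values[:10] = rng.uniform(1.0, 2.0, 10)
        rng.shuffle(values)
        vmap = VarianceMap(values.reshape(10, 10))
        roi = seed_roi(vmap, quantile=0.90)
        # sort-based oracle: strictly above the interpolated 90th percentile
        cutoff = np.sort(values)[89] + 0.1 * (np.sort(values)[90] - np.sort(values)[89])
        np.testing.assert_array_equal(roi.mask, vmap.values > cutoff)
        assert roi.n_pixels == 10

    def test_tiny_quantile_keeps_all_but_minimum(self, rng):
        values = rng.permutation(np.arange(1.0, 26.0)).reshape(5, 5)
        roi = seed_roi(VarianceMap(values), quantile=1e-9)
        assert roi.n_pixels == 24
        assert not roi.mask[values == values.min()].any()

    def test_deterministic(self, rng):
        vmap = VarianceMap(rng.uniform(0, 1, (12, 12)))
        a = seed_roi(vmap, 0.75)
        b = seed_roi(vmap, 0.75)
        np.testing.assert_array_equal(a.mask, b.mask)

    def test_all_zero_map_instructs_manual_roi(self):
        with pytest.raises(DegenerateError, match="manual"):
            seed_roi(VarianceMap(np.zeros((8, 8))), 0.75)


class TestEditRoi:
    def test_add_rectangle_pixel_count(self):
        roi = RegionOfInterest(np.zeros((10, 10), bool))
        rect = [(0, 0), (0, 3), (2, 3), (2, 0)]
        edited = edit_roi(roi, additions=[rect])
        assert edited.n_pixels == 12  # rows 0-2 x cols 0-3

    def test_add_then_remove_is_identity(self, rng):
        roi = RegionOfInterest(rng.random((10, 10)) > 0.5)
        poly = [(2, 2), (2, 7), (7, 7), (7, 2)]
        grown = edit_roi(roi, additions=[poly])
        shrunk = edit_roi(grown, removals=[poly])
        inner = edit_roi(roi, removals=[poly])
        np.testing.assert_array_equal(shrunk.mask, inner.mask)

    def test_removal_wins_on_overlap(self):
        roi = RegionOfInterest(np.zeros((10, 10), bool))
        poly = [(1, 1), (1, 5), (5, 5), (5, 1)]
        edited = edit_roi(roi, additions=[poly], removals=[poly])
        assert edited.n_pixels == 0

    def test_provenance_appended(self):
        roi = RegionOfInterest(np.zeros((5, 5), bool))
        edited = edit_roi(roi, additions=[[(0, 0), (0, 2), (2, 2)]])
        assert edited.provenance[-1]["op"] == "edit"

    def test_degenerate_polygon_rejected(self):
        roi = RegionOfInterest(np.zeros((5, 5), bool))
        with pytest.raises(ValidationError):
            edit_roi(roi, additions=[[(0, 0), (1, 1)]])

    def test_out_of_bounds_polygon_rejected(self):
        roi = RegionOfInterest(np.zeros((5, 5), bool))
        with pytest.raises(ValidationError, match="bounds"):
            edit_roi(roi, additions=[[(0, 0), (0, 9), (4, 9)]])


def _bimodal_run(rng, n=10_000, centers=(0.2, 0.8), spread=0.05):
    half = n // 2
    vals = np.concatenate(
        [rng.normal(centers[0], spread, half), rng.normal(centers[1], spread, n - half)]
    )
    side = int(np.sqrt(n))
    vals = np.abs(vals[: side * side])
    return ImageRun(vals.reshape(1, side, side)), RegionOfInterest(np.ones((side, side), bool))


class TestFitThreshold:
    def test_recovers_mixture_density_minimum(self, rng):
        """Two clusters at 0.2/0.8 (sigma 0.05): the analytic density minimum
        of the equal mixture is at 0.5, so the fit must land in 0.45-0.55."""
        grid = np.linspace(0, 1, 20_001)
        mixture = 0.5 * norm.pdf(grid, 0.2, 0.05) + 0.5 * norm.pdf(grid, 0.8, 0.05)
        interior = (grid > 0.3) & (grid < 0.7)
        analytic_min = grid[interior][np.argmin(mixture[interior])]
        assert analytic_min == pytest.approx(0.5, abs=1e-3)
        run, roi = _bimodal_run(rng)
        model = fit_threshold(run, roi)
        assert model.bimodality_ok
        assert 0.45 <= model.threshold <= 0.55

    def test_point_masses_threshold_between(self):
        vals = np.concatenate([np.full(50, 10.0), np.full(50, 200.0)])
        run = ImageRun(vals.reshape(1, 10, 10))
        model = fit_threshold(run, RegionOfInterest(np.ones((10, 10), bool)))
        assert 10 < model.threshold < 200
        assert model.mode_locations[0] < model.threshold < model.mode_locations[1]

    def test_unimodal_flags_not_bimodal(self, rng):
        vals = np.abs(rng.normal(5.0, 0.5, 400))
        run = ImageRun(vals.reshape(1, 20, 20))
        with pytest.warns(UserWarning, match="not bimodal"):
            model = fit_threshold(run, RegionOfInterest(np.ones((20, 20), bool)))
        assert not model.bimodality_ok

    def test_affine_intensity_equivariance(self, rng):
        """Fitting on a*I + b moves the threshold to a*t + b (up to grid step)."""
        run, roi = _bimodal_run(rng)
        t0 = fit_threshold(run, roi).threshold
        a, b = 37.0, 11.0
        scaled = run.with_intensities(a * run.intensities + b)
        t1 = fit_threshold(scaled, roi).threshold
        grid_step = a * 1.0 / 512  # generous bound on the KDE grid resolution
        assert t1 == pytest.approx(a * t0 + b, abs=4 * a * grid_step)

    def test_constant_roi_rejected(self):
        run = ImageRun(np.full((2, 5, 5), 9.0))
        with pytest.raises(DegenerateError):
            fit_threshold(run, RegionOfInterest(np.ones((5, 5), bool)))

    def test_empty_roi_rejected(self, rng):
        run = ImageRun(rng.uniform(0, 1, (2, 5, 5)))
        with pytest.raises(ValidationError):
            fit_threshold(run, RegionOfInterest(np.zeros((5, 5), bool)))


class TestClassifyRun:
    def test_matches_elementwise_oracle(self, rng):
        run = ImageRun(rng.uniform(0, 100, (4, 12, 12)))
        roi = RegionOfInterest(rng.random((12, 12)) > 0.3)
        model = _model(threshold=50.0)
        series = classify_run(run, roi, model)
        for f in range(4):
            for r in range(12):
                for c in range(12):
                    expected = roi.mask[r, c] and run.intensities[f, r, c] < 50.0
                    assert series.masks[f, r, c] == expected

    def test_all_above_threshold_all_false(self):
        run = ImageRun(np.full((3, 6, 6), 80.0))
        roi = RegionOfInterest(np.ones((6, 6), bool))
        assert not classify_run(run, roi, _model(10.0)).masks.any()

    def test_masks_subset_of_roi(self, rng):
        run = ImageRun(rng.uniform(0, 1, (5, 16, 16)))
        roi = RegionOfInterest(rng.random((16, 16)) > 0.6)
        series = classify_run(run, roi, _model(0.5))
        assert not (series.masks & ~roi.mask[None]).any()

    def test_boundary_pixel_is_tissue(self):
        run = ImageRun(np.full((1, 2, 2), 5.0))
        roi = RegionOfInterest(np.ones((2, 2), bool))
        assert not classify_run(run, roi, _model(5.0)).masks.any()


def _model(threshold):
    from vtshape.types import ThresholdModel

    return ThresholdModel(
        threshold=threshold,
        density_grid=(np.array([0.0, 1.0]), np.array([1.0, 1.0])),
        mode_locations=None,
        bimodality_ok=False,
    )
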