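"""Image path: empirical-line calibration, canopy masking, and grid
averaging on constructed rasters with known geometry."""

import numpy as np
import pandas as pd
import pytest

import canespec as cs
from canespec.imageprep import (
    AreaROI,
    CanopyMask,
    GridSpec,
    apply_calibration,
    extract_grid_means,
    fit_empirical_line,
    mask_canopy,
    read_raster,
    write_raster,
)
from canespec.synthetic import BANDS

RHO = np.array([0.05, 0.20, 0.40, 0.60])


def _linear_dns(slope=1000.0, offset=50.0):
    return {b: slope * RHO + offset for b in BANDS}


class TestEmpiricalLine:
    def test_noiseless_linear_recovery(self):
        lines = fit_empirical_line(_linear_dns(), RHO)
        for b in BANDS:
            assert lines[b].slope == pytest.approx(0.001, abs=1e-12)
            assert lines[b].intercept == pytest.approx(-0.05, abs=1e-10)
            assert lines[b].r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_tarps_pass_through_both_points(self):
        dns = {b: np.array([100.0, 700.0]) for b in BANDS}
        lines = fit_empirical_line(dns, np.array([0.1, 0.7]))
        ln = lines["G"]
        assert ln.slope * 100 + ln.intercept == pytest.approx(0.1)
        assert ln.slope * 700 + ln.intercept == pytest.approx(0.7)

    def test_noisy_fit_within_ols_sampling_bounds(self):
        """With additive DN noise the recovered slope stays within 4
        standard errors of the true line (closed-form OLS variance)."""
        rng = np.random.default_rng(0)
        true_slope_dn = 1000.0  # DN per unit reflectance
        sigma = 5.0
        # DN-on-reflectance is classical OLS (noise in y); the fitted
        # reflectance-on-DN slope is its reciprocal to first order, so
        # SE(slope) ~= [sigma/sqrt(S_rho_rho)] / true_slope_dn^2
        s_rho = np.sum((RHO - RHO.mean()) ** 2)
        se = sigma / np.sqrt(s_rho) / true_slope_dn**2
        misses = 0
        for _ in range(50):
            dn = true_slope_dn * RHO + 50 + rng.normal(0, sigma, size=4)
            lines = fit_empirical_line({b: dn for b in BANDS}, RHO)
            if abs(lines["R"].slope - 1 / true_slope_dn) > 4 * se:
                misses += 1
        assert misses <= 2  # ~4 sigma, a stray miss or two is expected

    def test_identical_dns_degenerate(self):
        dns = {b: np.full(4, 500.0) for b in BANDS}
        with pytest.raises(ValueError, match="degenerate"):
            fit_empirical_line(dns, RHO)

    def test_tarp_table_input(self):
        rows = [{"tarp_id": i, "reflectance": r, **{f"dn_{b}": 1000 * r + 50 for b in BANDS}}
                for i, r in enumerate(RHO)]
        lines = fit_empirical_line(pd.DataFrame(rows))
        assert lines["NIR"].slope == pytest.approx(0.001)


class TestApplyCalibration:
    def test_identity_line_returns_input(self):
        lines = {b: cs.CalibrationLine(b, 1.0, 0.0, 1.0, 2) for b in BANDS}
        dn = np.random.default_rng(0).random((5, 4, 4))
        np.testing.assert_array_equal(apply_calibration(dn, lines), dn)

    def test_hand_computed_value(self):
        lines = fit_empirical_line(_linear_dns(), RHO)
        out = apply_calibration(np.full((5, 2, 2), 650.0), lines)
        assert out[0, 0, 0] == pytest.approx(0.6)

    def test_dn_below_intercept_clips_to_zero(self):
        lines = fit_empirical_line(_linear_dns(), RHO)
        out = apply_calibration(np.full((5, 2, 2), 10.0), lines)  # maps to -0.04
        assert (out == 0.0).all()

    def test_nodata_propagates(self):
        lines = {b: cs.CalibrationLine(b, 0.001, 0.0, 1.0, 4) for b in BANDS}
        dn = np.full((5, 3, 3), 100.0)
        dn[2, 1, 1] = np.nan
        out = apply_calibration(dn, lines)
        assert np.isnan(out[2, 1, 1]) and not np.isnan(out[0, 0, 0])

    def test_missing_band_raises(self):
        lines = {b: cs.CalibrationLine(b, 1.0, 0.0, 1.0, 2) for b in BANDS[:-1]}
        with pytest.raises(ValueError, match="NIR"):
            apply_calibration(np.zeros((5, 2, 2)), lines)


def _canopy_raster():
    """10x10 scene: bright-NIR canopy rectangle rows 2:6, cols 3:8 on a
    soil background with NIR approx R (low NDVI)."""
    r = np.full((5, 10, 10), 0.18)
    r[BANDS.index("NIR")] = 0.20
    r[:, 2:6, 3:8] = 0.05
    r[BANDS.index("NIR"), 2:6, 3:8] = 0.60
    return r


class TestMaskCanopy:
    def test_bare_soil_gives_empty_mask(self):
        soil = np.full((5, 6, 6), 0.2)  # NIR == R -> NDVI 0
        assert mask_canopy(soil).mask.sum() == 0

    def test_known_rectangle_recovered_exactly(self):
        m = mask_canopy(_canopy_raster())
        expected = np.zeros((10, 10), bool)
        expected[2:6, 3:8] = True
        np.testing.assert_array_equal(m.mask, expected)

    def test_threshold_one_empties_mask(self):
        assert mask_canopy(_canopy_raster(), ndvi_threshold=1.0).mask.sum() == 0

    def test_raising_threshold_never_adds_pixels(self):
        r = np.random.default_rng(1).random((5, 12, 12)) * 0.6 + 0.01
        prev = mask_canopy(r, ndvi_threshold=0.0).mask
        for thr in (0.2, 0.4, 0.6, 0.8):
            cur = mask_canopy(r, ndvi_threshold=thr).mask
            assert not np.any(cur & ~prev)
            prev = cur

    def test_shadow_floor_drops_dark_pixels(self):
        r = _canopy_raster()
        r[:, 3, 4] *= 0.1  # darken one canopy pixel below the floor
        m = mask_canopy(r, shadow_brightness_floor=0.15)
        assert not m.mask[3, 4] and m.mask[2, 3]


class TestExtractGridMeans:
    def test_constant_raster_full_mask(self):
        r = np.full((5, 9, 9), 0.3)
        grids = GridSpec((AreaROI("a", 0, 9, 0, 9),))
        recs = extract_grid_means(r, CanopyMask(np.ones((9, 9), bool), 0.0, None), grids)
        assert len(recs) == 9
        for b in BANDS:
            np.testing.assert_allclose(recs[f"refl_{b}"], 0.3)

    def test_checkerboard_hand_computed_means(self):
        r = np.zeros((5, 4, 4))
        vals = np.arange(16, dtype=float).reshape(4, 4)
        for i in range(5):
            r[i] = vals
        mask = np.indices((4, 4)).sum(axis=0) % 2 == 0  # checkerboard
        grids = GridSpec((AreaROI("a", 0, 4, 0, 4),), grid_rows=2, grid_cols=2)
        recs = extract_grid_means(r, CanopyMask(mask, 0.0, None), grids)
        # grid 0 = rows 0:2 x cols 0:2, masked cells (0,0) and (1,1): mean of 0, 5
        assert recs.loc[0, "refl_B"] == pytest.approx(2.5)
        # grid 1 = rows 0:2 x cols 2:4, masked (0,2) and (1,3): mean of 2, 7
        assert recs.loc[1, "refl_B"] == pytest.approx(4.5)

    def test_default_layout_yields_324_records(self):
        rows = 60, 60
        r = np.random.default_rng(0).random((5, *rows)) * 0.5 + 0.01
        areas = tuple(
            AreaROI(f"a{i}{j}", 10 * i, 10 * (i + 1), 10 * j, 10 * (j + 1))
            for i in range(6) for j in range(6)
        )  # 36 areas
        recs = extract_grid_means(
            r, CanopyMask(np.ones(rows, bool), 0.0, None), GridSpec(areas)
        )
        assert len(recs) == 324
        assert recs["valid"].all()

    def test_empty_grid_flagged_not_dropped(self):
        r = np.full((5, 6, 6), 0.4)
        mask = np.zeros((6, 6), bool)
        mask[0, 0] = True
        grids = GridSpec((AreaROI("a", 0, 6, 0, 6),), grid_rows=2, grid_cols=2)
        recs = extract_grid_means(r, CanopyMask(mask, 0.0, None), grids)
        assert len(recs) == 4
        assert recs["valid"].tolist() == [True, False, False, False]
        assert recs.loc[1, "refl_B"] != recs.loc[1, "refl_B"]  # NaN

    def test_grid_means_bounded_by_pixel_extremes(self):
        r = np.random.default_rng(3).random((5, 8, 8))
        grids = GridSpec((AreaROI("a", 0, 8, 0, 8),), 2, 2)
        recs = extract_grid_means(r, CanopyMask(np.ones((8, 8), bool), 0.0, None), grids)
        for b in BANDS:
            assert (recs[f"refl_{b}"] >= r[BANDS.index(b)].min()).all()
            assert (recs[f"refl_{b}"] <= r[BANDS.index(b)].max()).all()

    def test_out_of_bounds_area_raises(self):
        grids = GridSpec((AreaROI("a", 0, 20, 0, 4),))
        with pytest.raises(ValueError, match="exceeds"):
            extract_grid_means(
                np.zeros((5, 8, 8)), CanopyMask(np.ones((8, 8), bool), 0.0, None), grids
            )


def test_calibration_commutes_with_extraction():
    """Calibrate-then-average equals average-then-transform, by
    linearity of the mean over each grid."""
    rng = np.random.default_rng(7)
    dn = rng.uniform(100, 900, size=(5, 12, 12))
    lines = fit_empirical_line(_linear_dns(), RHO)
    mask = CanopyMask(rng.random((12, 12)) > 0.3, 0.0, None)
    grids = GridSpec((AreaROI("a", 0, 12, 0, 12),), 3, 3)
    first = extract_grid_means(apply_calibration(dn, lines), mask, grids)
    second = extract_grid_means(dn, mask, grids)
    for b in BANDS:
        transformed = lines[b].slope * second[f"refl_{b}"] + lines[b].intercept
        np.testing.assert_allclose(first[f"refl_{b}"], transformed, atol=1e-12)


def test_gridspec_yaml_roundtrip():
    g = GridSpec((AreaROI("a1", 0, 10, 0, 12), AreaROI("a2", 10, 20, 0, 12)), 3, 3)
    assert GridSpec.from_yaml(g.to_yaml()) == g


def test_raster_tiff_roundtrip(tmp_path):
    r = np.random.default_rng(0).random((5, 7, 9)).astype(np.float32)
    path = tmp_path / "scene.tif"
    write_raster(path, r)
    back = read_raster(path)
    np.testing.assert_allclose(back, r, atol=1e-7)
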