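import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mesoqc import (
    FocusStack,
    RonchiConfig,
    RonchiContrastModel,
    best_focus_surface,
    build_contrast_map,
    chromatic_focal_offset,
    contrast_uniformity,
    depth_of_field_map,
    field_flatness,
    fit_tilt_plane,
    max_contrast_map,
    partition_grid,
    ronchi_config_for_sag,
    simulate_ronchi_stack,
    subregion_contrast,
)
from mesoqc.contrast import BestFocusSurface, ContrastMap3D
from mesoqc.optics import effective_magnification, tube_lens_magnification_scale

from conftest import contrast_oracle


class TestPartitionGrid:
    def test_camera_frame_splits_into_equal_subregions(self):
        g = partition_grid(5056, 2960, 32, 20)
        assert np.all(np.diff(g.col_bounds) == 158)
        assert np.all(np.diff(g.row_bounds) == 148)
        assert g.col_bounds[0] == 0 and g.col_bounds[-1] == 5056
        assert g.row_bounds[0] == 0 and g.row_bounds[-1] == 2960

    def test_single_subregion_covers_frame(self):
        g = partition_grid(100, 100, 1, 1)
        np.testing.assert_array_equal(g.col_bounds, [0, 100])
        np.testing.assert_array_equal(g.row_bounds, [0, 100])

    def test_floor_boundaries_for_uneven_split(self):
        g = partition_grid(10, 10, 3, 3)
        np.testing.assert_array_equal(g.col_bounds, [0, 3, 6, 10])
        assert np.diff(g.col_bounds).max() - np.diff(g.col_bounds).min() <= 1

    def test_more_subregions_than_pixels_rejected(self):
        with pytest.raises(ValueError):
            partition_grid(10, 10, 11, 2)


class TestSubregionContrast:
    def test_binary_pattern_gives_unity(self):
        v = np.tile([0.0, 1.0], 100)
        assert subregion_contrast(v) == pytest.approx(1.0)

    def test_constant_gives_zero(self):
        assert subregion_contrast(np.full(50, 5.0)) == 0.0

    def test_linear_ramp_matches_percentile_oracle(self):
        v = np.arange(1.0, 101.0)
        # P1 = 1.99, P99 = 99.01 under rank = 1 + q/100*(n-1)
        assert subregion_contrast(v) == pytest.approx((99.01 - 1.99) / (99.01 + 1.99))
        assert subregion_contrast(v) == pytest.approx(contrast_oracle(v))

    def test_zero_signal_flagged_nan(self):
        assert np.isnan(subregion_contrast(np.zeros(10)))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            subregion_contrast(np.array([1.0]))
        with pytest.raises(ValueError):
            subregion_contrast(np.array([1.0, -2.0]))
        with pytest.raises(ValueError):
            subregion_contrast(np.array([1.0, np.nan]))

    @given(st.integers(0, 2**31 - 1))
    @settings(deadline=None, max_examples=25)
    def test_gain_invariance_offset_monotonicity(self, seed):
        """Contrast is invariant under positive gain and strictly reduced
        by a positive offset."""
        rng = np.random.default_rng(seed)
        v = rng.uniform(1.0, 100.0, size=64)
        c = subregion_contrast(v)
        assert subregion_contrast(3.7 * v) == pytest.approx(c, rel=1e-12)
        assert subregion_contrast(v + 50.0) < c


class TestContrastMap:
    def test_matches_brute_force_subregion_loop(self):
        rng = np.random.default_rng(12)
        data = rng.integers(10, 5000, size=(4, 30, 40)).astype(np.uint16)
        stack = FocusStack(data=data, z_positions_um=np.arange(4.0) * 10)
        grid = partition_grid(40, 30, 4, 3)
        cmap = build_contrast_map(stack, grid)
        for k in range(4):
            for j in range(3):
                for i in range(4):
                    sub = data[k, grid.row_bounds[j]:grid.row_bounds[j + 1],
                               grid.col_bounds[i]:grid.col_bounds[i + 1]]
                    assert cmap.values[j, i, k] == contrast_oracle(sub)

    def test_constant_frames_give_zero_map(self):
        data = np.full((3, 20, 32), 500, dtype=np.uint16)
        stack = FocusStack(data=data, z_positions_um=np.arange(3.0))
        cmap = build_contrast_map(stack, partition_grid(32, 20, 4, 2))
        np.testing.assert_array_equal(cmap.values, 0.0)

    def test_output_shape_is_grid_by_planes(self):
        cfg = RonchiConfig(width_px=320, height_px=200, n_planes=61)
        stack, _ = simulate_ronchi_stack(cfg, seed=1)
        cmap = build_contrast_map(stack, partition_grid(320, 200, 32, 20))
        assert cmap.values.shape == (20, 32, 61)

    def test_saturated_subregions_flagged(self):
        data = np.full((2, 20, 20), 100, dtype=np.uint16)
        data[0, :10, :10] = 65535  # saturate one subregion in plane 0
        stack = FocusStack(data=data, z_positions_um=np.array([0.0, 10.0]))
        cmap = build_contrast_map(stack, partition_grid(20, 20, 2, 2))
        assert np.isnan(cmap.values[0, 0, 0])
        assert np.isfinite(cmap.values[0, 0, 1])

    def test_grid_mismatch_rejected(self):
        stack = FocusStack(data=np.zeros((2, 20, 20), dtype=np.uint16),
                           z_positions_um=np.array([0.0, 1.0]))
        with pytest.raises(ValueError):
            build_contrast_map(stack, partition_grid(30, 30, 2, 2))


def _gaussian_cmap(z0_map, z, w=40.0, peak=0.8, grid_wh=(64, 40)):
    grid = partition_grid(*grid_wh, z0_map.shape[1], z0_map.shape[0])
    vals = peak * np.exp(-((z[None, None, :] - z0_map[:, :, None]) ** 2) / (2 * w**2))
    return ContrastMap3D(values=vals, z_positions_um=z, grid=grid)


class TestBestFocusSurface:
    def test_symmetric_peak_at_sampled_z_is_exact(self):
        z = np.arange(0.0, 101.0, 10.0)
        cmap = _gaussian_cmap(np.full((2, 2), 50.0), z)
        surf = best_focus_surface(cmap, refine="parabolic")
        np.testing.assert_allclose(surf.z0_um, 50.0, atol=1e-9)

    def test_recovers_simulated_tilted_surface(self):
        cfg = RonchiConfig(width_px=160, height_px=100, n_planes=41, z_start_um=-200.0,
                           surface_coeffs=(10.0, 30.0, 0.0, 0.0, 0.0), noise_sd=0.0,
                           nx_sub=16, ny_sub=10)
        stack, truth = simulate_ronchi_stack(cfg, seed=1)
        cmap = build_contrast_map(stack, partition_grid(160, 100, 16, 10))
        surf = best_focus_surface(cmap)
        assert surf.valid_mask.all()
        assert np.abs(surf.z0_um - truth.z0_subregions_um).max() <= cfg.z_step_um / 2

    def test_boundary_peak_flagged_invalid(self):
        z = np.arange(0.0, 51.0, 10.0)
        vals = np.linspace(0.1, 0.9, len(z))[None, None, :] * np.ones((2, 2, 1))
        cmap = ContrastMap3D(values=vals, z_positions_um=z,
                             grid=partition_grid(20, 20, 2, 2))
        surf = best_focus_surface(cmap)
        assert not surf.valid_mask.any()

    def test_refinement_needs_three_planes(self):
        cmap = ContrastMap3D(values=np.ones((1, 1, 2)) * 0.5,
                             z_positions_um=np.array([0.0, 10.0]),
                             grid=partition_grid(4, 4, 1, 1))
        with pytest.raises(ValueError):
            best_focus_surface(cmap, refine="parabolic")

    def test_gaussian_refine_matches_truth_closely(self):
        z = np.arange(-100.0, 101.0, 10.0)
        cmap = _gaussian_cmap(np.array([[13.0, -27.0], [5.0, 41.0]]), z)
        surf = best_focus_surface(cmap, refine="gaussian")
        np.testing.assert_allclose(surf.z0_um, [[13.0, -27.0], [5.0, 41.0]], atol=1e-6)

    def test_z_shift_equivariance(self):
        """Shifting all focus positions by D shifts z0 by exactly D and
        leaves sag, DOF and C_max unchanged."""
        z = np.arange(-100.0, 101.0, 10.0)
        z0 = np.array([[13.0, -27.0, 3.0], [5.0, 41.0, -8.0], [0.0, 7.0, 19.0]])
        c1 = _gaussian_cmap(z0, z)
        c2 = ContrastMap3D(values=c1.values, z_positions_um=z + 55.0, grid=c1.grid)
        s1, s2 = best_focus_surface(c1), best_focus_surface(c2)
        np.testing.assert_allclose(s2.z0_um - s1.z0_um, 55.0, atol=1e-9)
        _, _, sag1, _ = field_flatness(s1)
        _, _, sag2, _ = field_flatness(s2)
        assert sag2 == pytest.approx(sag1, abs=1e-9)
        np.testing.assert_allclose(depth_of_field_map(c1), depth_of_field_map(c2), atol=1e-9)
        np.testing.assert_allclose(max_contrast_map(c1), max_contrast_map(c2))


class TestTiltPlaneAndFlatness:
    def _surface(self, z0, valid=None):
        ny, nx = z0.shape
        grid = partition_grid(nx * 10, ny * 10, nx, ny)
        mask = np.ones_like(z0, bool) if valid is None else valid
        return BestFocusSurface(z0_um=z0, peak_contrast=np.ones_like(z0),
                                valid_mask=mask, grid=grid,
                                z_positions_um=np.arange(5.0))

    def test_exact_plane_recovered(self):
        grid = partition_grid(80, 60, 8, 6)
        xn, yn = grid.normalized_centers()
        surf = self._surface(5.0 + 0.1 * xn + 0.2 * yn)
        a0, ax, ay = fit_tilt_plane(surf)
        assert (a0, ax, ay) == pytest.approx((5.0, 0.1, 0.2), abs=1e-9)

    def test_constant_surface_has_zero_slopes(self):
        a0, ax, ay = fit_tilt_plane(self._surface(np.full((4, 5), 7.0)))
        assert (a0, ax, ay) == pytest.approx((7.0, 0.0, 0.0), abs=1e-12)

    def test_symmetric_paraboloid_has_zero_slopes(self):
        grid = partition_grid(80, 60, 8, 6)
        xn, yn = grid.normalized_centers()
        # normal-equations oracle: on a symmetric grid, odd moments vanish
        surf = self._surface(30.0 * (xn**2 + yn**2))
        _, ax, ay = fit_tilt_plane(surf)
        assert ax == pytest.approx(0.0, abs=1e-9)
        assert ay == pytest.approx(0.0, abs=1e-9)

    def test_pure_tilt_gives_zero_sag(self):
        grid = partition_grid(80, 60, 8, 6)
        xn, yn = grid.normalized_centers()
        plane, det, sag, sag_rob = field_flatness(self._surface(3.0 + 12.0 * xn - 5.0 * yn))
        assert sag == pytest.approx(0.0, abs=1e-9)
        # detrended surface has no residual plane component
        refit = fit_tilt_plane(self._surface(det))
        assert abs(refit[1]) < 1e-9 and abs(refit[2]) < 1e-9

    def test_too_few_valid_entries_rejected(self):
        valid = np.zeros((4, 5), bool)
        valid[0, 0] = valid[0, 1] = True
        with pytest.raises(ValueError):
            fit_tilt_plane(self._surface(np.zeros((4, 5)), valid))


class TestDepthOfField:
    def test_gaussian_profile_matches_closed_form(self):
        z = np.arange(-150.0, 151.0, 10.0)
        w = 40.0
        cmap = _gaussian_cmap(np.zeros((3, 3)), z, w=w)
        dof = depth_of_field_map(cmap, rel_threshold=0.5)
        expected = 2 * w * np.sqrt(2 * np.log(2))
        np.testing.assert_allclose(dof, expected, rtol=0.05)

    def test_threshold_one_gives_vanishing_dof(self):
        z = np.arange(-150.0, 151.0, 10.0)
        dof = depth_of_field_map(_gaussian_cmap(np.zeros((2, 2)), z), rel_threshold=1.0)
        assert np.nanmax(dof) <= 10.0

    def test_zero_contrast_flagged(self):
        z = np.arange(-50.0, 51.0, 10.0)
        cmap = ContrastMap3D(values=np.zeros((2, 2, len(z))), z_positions_um=z,
                             grid=partition_grid(20, 20, 2, 2))
        assert np.isnan(depth_of_field_map(cmap)).all()


class TestMaxContrastAndUniformity:
    def test_single_plane_is_identity(self):
        vals = np.random.default_rng(0).uniform(0, 1, (3, 4, 1))
        cmap = ContrastMap3D(values=vals, z_positions_um=np.array([0.0]),
                             grid=partition_grid(40, 30, 4, 3))
        np.testing.assert_array_equal(max_contrast_map(cmap), vals[:, :, 0])

    def test_uniform_peak_recovered_and_tilt_invariant(self):
        base = ronchi_config_for_sag(0.0, width_px=160, height_px=100, n_planes=31,
                                     z_start_um=-150.0, noise_sd=0.0,
                                     nx_sub=16, ny_sub=10)
        tilted = ronchi_config_for_sag(0.0, width_px=160, height_px=100, n_planes=31,
                                       z_start_um=-150.0, noise_sd=0.0,
                                       nx_sub=16, ny_sub=10,
                                       surface_coeffs=(0.0, 40.0, 25.0, 0.0, 0.0))
        maps = []
        for cfg in (base, tilted):
            stack, _ = simulate_ronchi_stack(cfg, seed=2)
            cmap = build_contrast_map(stack, partition_grid(160, 100, 16, 10))
            maps.append(max_contrast_map(cmap))
        np.testing.assert_allclose(maps[0], 0.8, rtol=0.02)
        np.testing.assert_allclose(maps[1], maps[0], rtol=0.02)

    def test_uniformity_stats(self):
        m = np.array([[0.6, 1.0], [1.0, 0.6]])
        u = contrast_uniformity(m)
        assert u.mean == pytest.approx(0.8)
        assert u.sd == pytest.approx(0.2)
        assert u.cv == pytest.approx(0.25)
        const = contrast_uniformity(np.full((2, 2), 0.8))
        assert const.mean == pytest.approx(0.8) and const.cv == 0.0
        single = contrast_uniformity(np.array([[0.7]]))
        assert single.sd == 0.0
        with pytest.raises(ValueError):
            contrast_uniformity(np.full((2, 2), np.nan))


class TestChromaticOffsets:
    def _surf(self, z0):
        grid = partition_grid(80, 60, z0.shape[1], z0.shape[0])
        return BestFocusSurface(z0_um=z0, peak_contrast=np.ones_like(z0),
                                valid_mask=np.ones_like(z0, bool), grid=grid,
                                z_positions_um=np.arange(3.0))

    def test_identical_surfaces_zero_offset(self):
        z0 = np.random.default_rng(1).uniform(-10, 10, (6, 8))
        rep = chromatic_focal_offset({"a": self._surf(z0), "b": self._surf(z0.copy())}, "a")
        assert rep.offsets_um["b"] == 0.0

    def test_constant_shift_recovered_and_antisymmetric(self):
        z0 = np.random.default_rng(2).uniform(-10, 10, (6, 8))
        surfs = {"blue": self._surf(z0), "red": self._surf(z0 + 400.0)}
        rep = chromatic_focal_offset(surfs, "blue")
        assert rep.offsets_um["red"] == pytest.approx(400.0)
        assert rep.pairwise_offsets_um[("red", "blue")] == pytest.approx(
            -rep.pairwise_offsets_um[("blue", "red")]
        )
        assert rep.pairwise_offsets_um[("red", "red")] == 0.0

    def test_grid_mismatch_and_missing_reference(self):
        z0 = np.zeros((4, 4))
        with pytest.raises(ValueError):
            chromatic_focal_offset({"a": self._surf(z0)}, "missing")
        with pytest.raises(ValueError):
            chromatic_focal_offset(
                {"a": self._surf(z0), "b": self._surf(np.zeros((4, 5)))}, "a"
            )


class TestTubeLensScale:
    def test_nonstandard_tube_lens_rescales_magnification(self):
        assert tube_lens_magnification_scale(180.0, 200.0) == pytest.approx(0.9)
        assert effective_magnification(5.0, 180.0, 200.0) == pytest.approx(4.5)
        with pytest.raises(ValueError):
            tube_lens_magnification_scale(-1.0, 200.0)


class TestModelResults:
    def test_fit_produces_consistent_report(self, small_ronchi):
        cfg, stack, truth = small_ronchi
        res = RonchiContrastModel(stack, nx_sub=cfg.nx_sub, ny_sub=cfg.ny_sub).fit()
        assert res.sag_um >= 0
        assert res.report.cmax_map.shape == (cfg.ny_sub, cfg.nx_sub)
        assert "sag" in res.summary()
        d = res.to_dict()
        assert {"sag_um", "cmax_map", "plane_fit"} <= set(d)
        frame = res.to_frame()
        assert len(frame) == cfg.nx_sub * cfg.ny_sub
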