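"""Vessel sharpness/length and AHA 17-segment polar maps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

import mocorr as mc
from mocorr.metrics import PolarMap, segment_masks
from mocorr.phantom import Centerline, DefectSpec, LVGeometry, PhantomConfig


def _straight_tube(n=48, radius_vox=3, value=1.0, background=0.0,
                   length_frac=0.8):
    """Axis-aligned tube along z through the volume centre (hard edge)."""
    vol = np.full((n, n, n), background)
    xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    mask = (xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= radius_vox ** 2
    z0, z1 = int(0.1 * n), int(0.1 * n + length_frac * n)
    vol[mask, z0:z1] = value
    pts = np.stack([np.full(z1 - z0, (n // 2 + 0.5) * 2.0),
                    np.full(z1 - z0, (n // 2 + 0.5) * 2.0),
                    (np.arange(z0, z1) + 0.5) * 2.0], axis=1)
    cl = Centerline("tube", pts, np.full(len(pts), radius_vox * 2.0))
    return vol, cl


class TestSharpness:
    def test_ideal_step_tube_scores_100(self):
        vol, cl = _straight_tube()
        m = mc.vessel_sharpness(vol, cl, voxel_mm=2.0)
        assert m.sharpness_pct == pytest.approx(100.0, abs=1e-6)

    def test_intensity_scaling_invariance(self):
        vol, cl = _straight_tube()
        a = mc.vessel_sharpness(vol, cl, 2.0).sharpness_pct
        b = mc.vessel_sharpness(7.3 * vol, cl, 2.0).sharpness_pct
        assert a == pytest.approx(b, rel=1e-12)

    def test_blurred_tube_matches_analytic_profile_oracle(self):
        # blur with FWHM = 2 voxels, compare against a brute-force
        # computation of the blurred disc profile on a fine grid
        sigma_vox = 2.0 / 2.3548
        vol, cl = _straight_tube(radius_vox=4)
        blurred = ndimage.gaussian_filter(vol, sigma_vox)
        got = mc.vessel_sharpness(blurred, cl, 2.0).sharpness_pct

        # brute-force oracle: the voxelised disc is a piecewise-constant
        # continuous image; convolve it with the Gaussian on a 0.05-voxel
        # grid, then push the profile through the same measurement chain as
        # the estimator (voxel-centre sampling, linear interpolation to
        # 0.25-voxel steps, central differences)
        from scipy.signal import fftconvolve
        up = 20                                  # 1/0.05 voxel
        n = 48
        xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        mask = ((xx - n // 2) ** 2 + (yy - n // 2) ** 2 <= 4 ** 2).astype(float)
        fine_img = np.kron(mask, np.ones((up, up)))
        ax = (np.arange(-6 * up, 6 * up) + 0.5) / up
        gx, gy = np.meshgrid(ax, ax, indexing="ij")
        g = np.exp(-(gx ** 2 + gy ** 2) / (2 * sigma_vox ** 2))
        g /= g.sum()
        prof2d = fftconvolve(fine_img, g, mode="same")
        centre_row = prof2d[:, (n // 2) * up + up // 2]
        fine_coords = (np.arange(n * up) + 0.5) / up - 0.5   # voxel units
        vox_grid = np.arange(n, dtype=float)
        p_vox = np.interp(vox_grid, fine_coords, centre_row)
        xs = np.arange(n // 2 - 4, n // 2 + 4.01, 0.25)
        p = np.interp(xs, vox_grid, p_vox)
        deriv = np.gradient(p, 0.25)
        oracle = np.abs(deriv).max() / p[len(xs) // 2] * 100.0
        assert got == pytest.approx(oracle, rel=0.02)

    def test_rotation_invariance_within_tolerance(self):
        # band-limit the tube so rotation resampling is faithful
        vol, cl = _straight_tube(radius_vox=4)
        sm = ndimage.gaussian_filter(vol, 1.5)
        a = mc.vessel_sharpness(sm, cl, 2.0).sharpness_pct
        # rotate volume and centerline by 30 deg about the z axis
        rot = ndimage.rotate(sm, 30.0, axes=(0, 1), reshape=False, order=3)
        th = np.deg2rad(-30.0)
        c = np.array([48 / 2 * 2.0, 48 / 2 * 2.0, 0.0])
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1]])
        pts = (cl.points_mm - c) @ R.T + c
        cl_rot = Centerline("tube", pts, cl.radius_mm)
        b = mc.vessel_sharpness(rot, cl_rot, 2.0).sharpness_pct
        assert b == pytest.approx(a, rel=0.03)

    def test_zero_centreline_intensity_rejected(self):
        vol, cl = _straight_tube(value=0.0)
        with pytest.raises(ValueError):
            mc.vessel_sharpness(vol, cl, 2.0)


class TestVesselLength:
    def test_fully_visible_tube_full_length(self):
        vol, cl = _straight_tube()
        total = cl.arc_length_mm[-1]
        got = mc.vessel_length(vol, cl, 2.0)
        assert abs(got - total) <= 2.0 + 1e-9

    def test_contrast_loss_truncates_length(self):
        vol, cl = _straight_tube()
        # zero the lumen beyond 40 mm of arc length
        arc = cl.arc_length_mm
        cut = cl.points_mm[np.searchsorted(arc, 40.0)]
        zcut = int(cut[2] / 2.0)
        vol[:, :, zcut:] = 0.0
        got = mc.vessel_length(vol, cl, 2.0)
        assert abs(got - 40.0) <= 2.0 + 1e-9

    def test_invisible_origin_gives_zero(self):
        vol, cl = _straight_tube()
        vol[:, :, :30] = 0.0
        assert mc.vessel_length(vol, cl, 2.0) == 0.0


def _uniform_myo_phantom(defect=None):
    return mc.build_phantom(PhantomConfig(matrix=48, defect=defect,
                                          stenosis=None))


class TestPolarMap:
    def test_uniform_myocardium_gives_equal_segments(self):
        ph = _uniform_myo_phantom()
        pm = mc.polar_map_17(ph.activity_volume, ph.lv_geometry,
                             ph.myocardium_mask, 2.0)
        assert np.all(np.isfinite(pm.values))
        assert np.ptp(pm.values) / pm.values.mean() < 1e-6

    def test_inferior_mid_defect_lands_in_segment_10(self):
        ph = _uniform_myo_phantom(DefectSpec(angle_deg=180.0,
                                             transmurality=0.2))
        pm = mc.polar_map_17(ph.activity_volume, ph.lv_geometry,
                             ph.myocardium_mask, 2.0)
        assert int(np.nanargmin(pm.values)) + 1 == 10
        remote = np.nanmean(np.delete(pm.values, [8, 9, 10]))
        assert pm.values[9] < 0.5 * remote

    def test_rotated_defect_moves_to_adjacent_segment(self):
        ph = _uniform_myo_phantom(DefectSpec(angle_deg=240.0,
                                             transmurality=0.2))
        pm = mc.polar_map_17(ph.activity_volume, ph.lv_geometry,
                             ph.myocardium_mask, 2.0)
        assert int(np.nanargmin(pm.values)) + 1 == 11   # mid inferolateral

    def test_segments_partition_the_myocardium(self):
        ph = _uniform_myo_phantom()
        lab = segment_masks(ph.shape, 2.0, ph.lv_geometry,
                            ph.myocardium_mask)
        assert np.all((lab > 0) == ph.myocardium_mask)
        assert set(np.unique(lab[ph.myocardium_mask])) <= set(range(1, 18))

    def test_wrong_segment_count_rejected(self):
        with pytest.raises(ValueError):
            PolarMap(values=np.ones(16))


class TestRelativeIncrease:
    def test_equal_maps_give_zero(self):
        pm = PolarMap(np.linspace(1, 2, 17))
        out = mc.relative_increase(pm, pm)
        assert np.allclose(out.values, 0.0)

    def test_uniform_8_percent(self):
        nmc = PolarMap(np.full(17, 2.0))
        mcm = PolarMap(np.full(17, 2.0 * 1.08))
        out = mc.relative_increase(mcm, nmc)
        assert np.allclose(out.values, 8.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_direct_formula(self, seed):
        rng = np.random.default_rng(seed)
        a = PolarMap(rng.random(17) + 0.1)
        b = PolarMap(rng.random(17) + 0.1)
        out = mc.relative_increase(a, b)
        assert np.allclose(out.values, 100.0 * (a.values - b.values) / b.values)

    def test_zero_reference_segment_is_missing(self):
        nmc = PolarMap(np.ones(17))
        nmc.values[4] = 0.0
        out = mc.relative_increase(PolarMap(np.ones(17)), nmc)
        assert np.isnan(out.values[4])
        assert np.all(np.isfinite(np.delete(out.values, 4)))
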