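"""Iterative SENSE, non-rigid registration, motion-compensated CMRA."""

import numpy as np
import pytest
from scipy import ndimage

import mocorr as mc
from mocorr.linops import CoilOp, GridSampleOp, WarpOp, fftc
from mocorr.motion import MotionTable, OutlierRule
from mocorr.mr_recon import ReconVolume, _weighted_sense
from mocorr.utils import nrmse


def _static_table(n):
    return MotionTable(fh_mm=np.zeros(n), rl_mm=np.zeros(n),
                       score=np.ones(n), reference_beat=0)


def _dot(a, b):
    return np.vdot(np.asarray(a).ravel(), np.asarray(b).ravel())


class TestAdjointness:
    """Dot-product tests: <Ax, y> == <x, A^H y> for every operator."""

    def test_warp_operator(self, rng):
        fld = rng.standard_normal((3, 8, 9, 10)) * 1.5
        op = WarpOp(fld)
        x = rng.standard_normal((8, 9, 10)) + 1j * rng.standard_normal((8, 9, 10))
        y = rng.standard_normal((8, 9, 10)) + 1j * rng.standard_normal((8, 9, 10))
        lhs = _dot(op.forward(x), y)
        rhs = _dot(x, op.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_coil_operator(self, rng):
        sens = rng.standard_normal((4, 6, 6, 6)) + 1j * rng.standard_normal((4, 6, 6, 6))
        op = CoilOp(sens)
        x = rng.standard_normal((6, 6, 6)) + 1j * rng.standard_normal((6, 6, 6))
        y = rng.standard_normal((4, 6, 6, 6)) + 1j * rng.standard_normal((4, 6, 6, 6))
        lhs = _dot(op.forward(x), y)
        rhs = _dot(x, op.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_sampling_operator(self, rng):
        mask = (rng.random((8, 1, 8)) > 0.5).astype(float)
        op = GridSampleOp(mask)
        x = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        y = rng.standard_normal((8, 8, 8)) + 1j * rng.standard_normal((8, 8, 8))
        lhs = _dot(op.forward(x), y)
        rhs = _dot(x, op.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_composed_gmd_forward(self, rng):
        """warp -> coil -> Fourier -> sample against its adjoint chain."""
        shape = (8, 8, 8)
        fld = rng.standard_normal((3,) + shape)
        warp = WarpOp(fld)
        sens = rng.standard_normal((3,) + shape) + 1j * rng.standard_normal((3,) + shape)
        coil = CoilOp(sens)
        mask = (rng.random(shape) > 0.4).astype(float)

        def fwd(x):
            return mask[None] * fftc(coil.forward(warp.forward(x)), axes=(1, 2, 3))

        def adj(y):
            from mocorr.linops import ifftc
            return warp.adjoint(coil.adjoint(ifftc(mask[None] * y, axes=(1, 2, 3))))

        x = rng.standard_normal(shape) + 1j * rng.standard_normal(shape)
        y = rng.standard_normal((3,) + shape) + 1j * rng.standard_normal((3,) + shape)
        lhs = _dot(fwd(x), y)
        rhs = _dot(x, adj(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-10


class TestSense:
    def test_single_coil_full_sampling_equals_ifft(self, tiny_static_acq):
        a = tiny_static_acq
        mt = _static_table(a["traj"].n_interleaves)
        bins = mc.assign_bins(mt, 1, OutlierRule(method="none"))
        rec = mc.sense_bin(a["kspace"], bins, a["coils"], 0, n_iter=10)
        assert nrmse(a["phantom"].mr_volume, rec.magnitude) < 1e-8

    def test_undersampled_multicoil_recovers_object(self, small_phantom):
        ph = small_phantom
        traj = mc.make_trajectory((64, 64), 24)
        tr = mc.simulate_breathing(traj.n_interleaves, amplitude=0.0)
        coils = mc.simulate_coils(ph.shape, 8)
        ksp, _ = mc.acquire_cmra(ph, mc.MotionModel(tr), tr, traj, coils, 0.0)
        w = np.ones(traj.n_interleaves)
        w[1::2] = 0.0                       # discard every other interleaf
        rec = _weighted_sense(ksp, coils, w, 15, 1e-12, "test")
        assert nrmse(ph.mr_volume, rec.magnitude) < 0.08
        r = rec.residuals
        assert r[-1] == min(r) and r[-1] < r[0]

    def test_zero_weight_bin_rejected(self, tiny_static_acq):
        a = tiny_static_acq
        n = a["traj"].n_interleaves
        mt = _static_table(n)
        bins = mc.assign_bins(mt, 1, OutlierRule(method="none"))
        bins.weights[:] = 0.0
        with pytest.raises(ValueError):
            mc.sense_bin(a["kspace"], bins, a["coils"], 0)


class TestRegisterBins:
    def test_identical_images_give_zero_field(self, tiny_phantom):
        img = ReconVolume(tiny_phantom.mr_volume.astype(complex), 2.0)
        fs = mc.register_bins([img, img], reference=0)
        assert np.max(np.abs(fs.fields_mm[1])) / 2.0 < 0.1   # voxels

    def test_known_translation_recovered(self, small_phantom):
        truth = small_phantom.mr_volume
        shifted = np.roll(truth, 2, axis=2)      # 2 voxels toward the head
        imgs = [ReconVolume(truth.astype(complex), 2.0),
                ReconVolume(shifted.astype(complex), 2.0)]
        fs = mc.register_bins(imgs, reference=0)
        heart = _heart_mask(small_phantom)
        err = np.linalg.norm(
            fs.fields_mm[1][:, heart] - np.array([0, 0, -4.0])[:, None],
            axis=0)
        assert err.mean() / 2.0 < 0.5            # voxels

    def test_smooth_synthetic_deformation_recovered(self, small_phantom):
        ph = small_phantom
        model = mc.MotionModel(mc.simulate_breathing(2, amplitude=0.0),
                               nonrigid=True)
        fld = model.displacement_field(-8.0, 2.0, ph.shape, 2.0)
        moved = mc.warp_volume(ph.mr_volume, fld, 2.0)
        imgs = [ReconVolume(ph.mr_volume.astype(complex), 2.0),
                ReconVolume(moved.astype(complex), 2.0)]
        fs = mc.register_bins(imgs, reference=0)
        heart = _heart_mask(ph)
        # moved(v) = ref(v - d(v)) for slowly varying d -> pull field ~ -d
        err = np.linalg.norm(fs.fields_mm[1][:, heart] + fld[:, heart], axis=0)
        assert np.median(err) / 2.0 < 1.0        # voxels

    def test_needs_two_bins(self, tiny_phantom):
        img = ReconVolume(tiny_phantom.mr_volume.astype(complex), 2.0)
        with pytest.raises(ValueError):
            mc.register_bins([img], reference=0)


def _heart_mask(ph):
    lv = ph.lv_geometry
    n = ph.shape[0]
    ax = (np.arange(n) + 0.5) * ph.voxel_size[0]
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    return ((np.hypot(xx - lv.center_xy[0], yy - lv.center_xy[1])
             < lv.r_outer + 10)
            & (zz > lv.apex_z - 10) & (zz < lv.base_z + 10))


class TestMocomp:
    def test_identity_fields_single_bin_equals_sense(self, tiny_static_acq):
        a = tiny_static_acq
        n = a["traj"].n_interleaves
        mt = _static_table(n)
        bins = mc.assign_bins(mt, 1, OutlierRule(method="none"))
        fields = mc.DeformationFieldSet(
            fields_mm=np.zeros((1, 3) + a["phantom"].shape),
            reference_bin=0, voxel_mm=2.0)
        sense = mc.sense_bin(a["kspace"], bins, a["coils"], 0, n_iter=10)
        gmd = mc.mocomp_cmra(a["kspace"], bins, a["coils"], fields, n_iter=10)
        assert nrmse(sense.magnitude, gmd.magnitude) < 1e-8

    def test_translation_motion_corrected_with_true_fields(self, small_phantom):
        ph = small_phantom
        traj = mc.make_trajectory((64, 64), 24)
        ni = traj.n_interleaves
        trace = mc.simulate_breathing(ni, amplitude=10.0,
                                      deep_breath_prob=0.0, seed=9)
        model = mc.MotionModel(trace)
        coils = mc.simulate_coils(ph.shape, 8)
        ksp, _ = mc.acquire_cmra(ph, model, trace, traj, coils, 0.0)
        mt = MotionTable(trace.fh_mm, trace.rl_mm, np.ones(ni), 0)
        bins = mc.assign_bins(mt, 4, OutlierRule(method="none"))
        ksp_c = mc.correct_translational(ksp, mt, bins)
        fields = mc.translation_field_set(bins, ph.shape, 2.0)
        mc_img = mc.mocomp_cmra(ksp_c, bins, coils, fields, n_iter=15)
        nmc_img = mc.recon_nmc(ksp, coils, n_iter=15)

        # reference position = bin-0 centre; compare against the phantom
        # moved there (spectral shift: the acquisition's translation model)
        dfh = bins.fh_centers[0]
        drl = bins.rl_centers[0]
        truth = np.abs(mc.deform_phantom_to(ph, model, dfh, drl,
                                            spectral=True).mr)
        e_mc = nrmse(truth, mc_img.magnitude)
        e_nmc = nrmse(truth, nmc_img.magnitude)
        assert e_mc < e_nmc
        # motion-free comparison bound
        tr0 = mc.simulate_breathing(ni, amplitude=0.0)
        ksp0, _ = mc.acquire_cmra(ph, mc.MotionModel(tr0), tr0, traj, coils, 0.0)
        e_free = nrmse(ph.mr_volume, mc.recon_nmc(ksp0, coils, n_iter=15).magnitude)
        assert e_mc < 1.5 * max(e_free, 0.02)

    def test_zero_motion_mc_equals_nmc(self, tiny_static_acq):
        a = tiny_static_acq
        n = a["traj"].n_interleaves
        mt = _static_table(n)
        bins = mc.assign_bins(mt, 1, OutlierRule(method="none"))
        ksp_c = mc.correct_translational(a["kspace"], mt, bins)
        fields = mc.DeformationFieldSet(
            fields_mm=np.zeros((1, 3) + a["phantom"].shape),
            reference_bin=0, voxel_mm=2.0)
        mc_img = mc.mocomp_cmra(ksp_c, bins, a["coils"], fields, n_iter=10)
        nmc_img = mc.recon_nmc(a["kspace"], a["coils"], n_iter=10)
        assert nrmse(nmc_img.magnitude, mc_img.magnitude) < 1e-8

    def test_missing_field_rejected(self, tiny_static_acq):
        a = tiny_static_acq
        n = a["traj"].n_interleaves
        mt = _static_table(n)
        bins = mc.assign_bins(mt, 1, OutlierRule(method="none"))
        fields = mc.DeformationFieldSet(
            fields_mm=np.zeros((0, 3) + a["phantom"].shape),
            reference_bin=0, voxel_mm=2.0)
        with pytest.raises((ValueError, IndexError)):
            mc.mocomp_cmra(a["kspace"], bins, a["coils"], fields)
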