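"""PET projector, emission simulation, OSEM and RTA motion correction."""

import numpy as np
import pytest

import mocorr as mc
from mocorr.motion import MotionTable, OutlierRule
from mocorr.mr_recon import DeformationFieldSet, ReconVolume
from mocorr.pet import PETGeometry, Projector, invert_field, osem
from mocorr.utils import nrmse


def _disc_volume(n=32, nz=8, radius=10.0, soft=True):
    xx, yy = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    d = np.sqrt((xx - (n - 1) / 2) ** 2 + (yy - (n - 1) / 2) ** 2)
    sl = np.clip(radius + 0.5 - d, 0, 1) if soft else (d <= radius).astype(float)
    return np.repeat(sl[:, :, None], nz, axis=2)


@pytest.fixture(scope="module")
def disc_geom():
    return PETGeometry(n_angles=64, n_rad=32, rad_spacing_mm=2.0, voxel_mm=2.0)


@pytest.fixture(scope="module")
def disc_projector(disc_geom):
    return Projector(disc_geom, (32, 32, 8))


class TestProjector:
    def test_central_ray_matches_chord_length(self, disc_geom, disc_projector):
        vol = _disc_volume(radius=10.0)
        sino = disc_projector.forward(vol, psf_fwhm_mm=0.0)
        # chord through the centre of a unit disc of radius 10 vox = 20 mm
        assert sino[0, 0, 16] == pytest.approx(2 * 10 * 2.0, rel=0.02)

    def test_zero_volume_projects_to_zero(self, disc_projector):
        assert np.all(disc_projector.forward(np.zeros((32, 32, 8))) == 0)

    def test_projector_adjointness(self, disc_projector, rng):
        x = rng.standard_normal((32, 32, 8))
        y = rng.standard_normal((8, 64, 32))
        for psf in (0.0, 4.5):
            lhs = np.sum(disc_projector.forward(x, psf) * y)
            rhs = np.sum(x * disc_projector.adjoint(y, psf))
            assert abs(lhs - rhs) / abs(lhs) < 1e-10

    def test_empty_geometry_rejected(self):
        with pytest.raises(ValueError):
            Projector(PETGeometry(n_angles=1), (16, 16, 4))


class TestSimulatePet:
    def _bins(self, fh):
        mt = MotionTable(fh, 0.3 * fh, np.ones(len(fh)), 0)
        return mc.assign_bins(mt, 4, OutlierRule(method="none"))

    def test_zero_mu_gives_unit_attenuation(self, tiny_phantom):
        ph = tiny_phantom
        import dataclasses
        ph0 = dataclasses.replace(ph, mu_map=np.zeros(ph.shape))
        tr = mc.simulate_breathing(40, amplitude=0.0)
        bins = self._bins(np.zeros(40))
        geom = PETGeometry(n_angles=32, n_rad=32)
        sinos, _ = mc.simulate_pet(ph0, mc.MotionModel(tr), bins, 1e5, geom)
        assert np.all(sinos.att == 1.0)

    def test_total_counts_within_poisson_error(self, tiny_phantom):
        tr = mc.simulate_breathing(40, amplitude=10.0, deep_breath_prob=0.0,
                                   seed=3)
        bins = self._bins(tr.fh_mm)
        geom = PETGeometry(n_angles=32, n_rad=32)
        total = 2e5
        sinos, _ = mc.simulate_pet(tiny_phantom, mc.MotionModel(tr), bins,
                                   total, geom, seed=7)
        assert abs(sinos.counts.sum() - total) < 3 * np.sqrt(total)

    def test_static_bins_have_equal_means(self, tiny_phantom):
        tr = mc.simulate_breathing(40, amplitude=0.0)
        bins = self._bins(np.zeros(40))
        geom = PETGeometry(n_angles=32, n_rad=32)
        sinos, _ = mc.simulate_pet(tiny_phantom, mc.MotionModel(tr), bins,
                                   4e5, geom, seed=1)
        per_bin = sinos.counts.reshape(4, -1).sum(axis=1)
        # equal time fractions, zero motion: counts agree to Poisson error
        assert np.ptp(per_bin) < 8 * np.sqrt(per_bin.mean())

    def test_attenuation_in_unit_interval(self, tiny_phantom):
        tr = mc.simulate_breathing(40, amplitude=5.0, deep_breath_prob=0.0)
        bins = self._bins(tr.fh_mm)
        geom = PETGeometry(n_angles=32, n_rad=32)
        sinos, _ = mc.simulate_pet(tiny_phantom, mc.MotionModel(tr), bins,
                                   1e5, geom)
        assert sinos.att.min() > 0.0
        assert sinos.att.max() <= 1.0


class TestWarpMumap:
    def test_zero_fields_keep_reference(self, tiny_phantom):
        fs = DeformationFieldSet(np.zeros((3, 3) + tiny_phantom.shape), 0, 2.0)
        mm = mc.warp_mumap(tiny_phantom.mu_map, fs)
        for b in range(3):
            assert np.array_equal(mm.per_bin[b], tiny_phantom.mu_map)

    def test_translation_field_matches_shift(self, tiny_phantom):
        fs = DeformationFieldSet(np.zeros((2, 3) + tiny_phantom.shape), 0, 2.0)
        fs.fields_mm[1, 2] = -4.0           # pull field: object moves +2 vox
        mm = mc.warp_mumap(tiny_phantom.mu_map, fs)
        rolled = np.roll(tiny_phantom.mu_map, 2, axis=2)
        interior = (slice(3, -3),) * 3
        assert np.allclose(mm.per_bin[1][interior], rolled[interior])
        assert mm.per_bin[1].min() >= 0


class TestOsem:
    def test_noiseless_disc_recovered(self, disc_geom, disc_projector):
        vol = _disc_volume()
        y = disc_projector.forward(vol, 0.0)
        rec = osem(y, np.ones_like(y), disc_geom, n_iter=15, n_subsets=8,
                   psf_fwhm_mm=0.0, projector=disc_projector)
        assert nrmse(vol, rec.magnitude) < 0.05

    def test_zero_sinogram_gives_zero_image(self, disc_geom, disc_projector):
        y = np.zeros((8, 64, 32))
        rec = osem(y, np.ones_like(y), disc_geom, n_iter=1, n_subsets=4,
                   projector=disc_projector)
        assert np.all(rec.magnitude == 0)

    def test_mlem_conserves_total_counts(self, disc_geom, disc_projector):
        vol = _disc_volume()
        att = np.exp(-disc_projector.forward(0.005 * (vol > 0), 0.0))
        y_mean = att * disc_projector.forward(vol, 0.0)
        y = np.random.default_rng(0).poisson(20 * y_mean).astype(float)
        x = np.ones((32, 32, 8))
        for it in range(1, 4):
            rec = osem(y, att, disc_geom, n_iter=it, n_subsets=1,
                       psf_fwhm_mm=0.0, projector=disc_projector)
            fp = att * disc_projector.forward(rec.magnitude, 0.0)
            assert abs(fp.sum() - y.sum()) / y.sum() < 1e-3

    def test_ignoring_attenuation_biases_centre_low(self, disc_geom,
                                                    disc_projector):
        vol = _disc_volume()
        att = np.exp(-disc_projector.forward(0.0096 * (vol > 0.5), 0.0))
        y = att * disc_projector.forward(vol, 0.0)
        rec_no_att = osem(y, np.ones_like(y), disc_geom, n_iter=5,
                          n_subsets=8, psf_fwhm_mm=0.0,
                          projector=disc_projector)
        centre = rec_no_att.magnitude[14:18, 14:18, 4].mean()
        assert centre < 0.95 * vol[14:18, 14:18, 4].mean()

    def test_subsets_reduced_with_warning(self, disc_projector, disc_geom):
        vol = _disc_volume()
        y = disc_projector.forward(vol, 0.0)
        with pytest.warns(UserWarning):
            osem(y, np.ones_like(y), disc_geom, n_iter=1, n_subsets=999,
                 projector=disc_projector)


class TestRta:
    def test_identity_combination(self):
        img = ReconVolume(np.random.default_rng(0).random((16, 16, 8)).astype(complex), 2.0)
        fs = DeformationFieldSet(np.zeros((3, 3, 16, 16, 8)), 0, 2.0)
        out = mc.rta_combine([img, img, img], fs)
        assert np.allclose(out.magnitude, img.magnitude)

    def test_field_inversion_roundtrip(self, rng):
        from scipy.ndimage import gaussian_filter
        fld = np.stack([gaussian_filter(rng.standard_normal((16, 16, 16)), 3)
                        for _ in range(3)]) * 4.0
        inv = invert_field(fld, voxel=2.0)
        # composing g then h should be near identity in the interior
        from mocorr.linops import WarpOp
        comp = np.stack([WarpOp(inv / 2.0).forward(fld[c] / 2.0)
                         for c in range(3)]) + inv / 2.0
        interior = (slice(None), slice(3, -3), slice(3, -3), slice(3, -3))
        assert np.abs(comp[interior]).max() < 0.15   # voxels

    def test_rta_preserves_total_activity(self, rng):
        from scipy.ndimage import gaussian_filter
        base = gaussian_filter(rng.random((24, 24, 12)), 2)
        base[:3] = base[-3:] = 0
        imgs = [ReconVolume(base.astype(complex), 2.0) for _ in range(2)]
        fs = DeformationFieldSet(np.zeros((2, 3, 24, 24, 12)), 0, 2.0)
        fs.fields_mm[1, 2] = -2.0
        out = mc.rta_combine(imgs, fs)
        assert out.magnitude.sum() == pytest.approx(base.sum(), rel=0.01)

    def test_missing_bin_rejected(self):
        img = ReconVolume(np.ones((8, 8, 4)).astype(complex), 2.0)
        fs = DeformationFieldSet(np.zeros((3, 3, 8, 8, 4)), 0, 2.0)
        with pytest.raises(ValueError):
            mc.rta_combine([img, img], fs)
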