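"""Respiratory-binned PET simulation and motion-corrected reconstruction.

The scanner is modelled as a stack-of-2D parallel-beam system: each
transaxial slice (short-axis plane, slice axis = FH) is projected over
``n_angles`` views with ray-driven bilinear sampling, assembled once as a
sparse matrix so the back-projector is the exact transpose.  Emission data
are Poisson counts through the four-class attenuation map; reconstruction
is attenuation-corrected OSEM with optional radial Gaussian PSF modelling,
and motion correction follows reconstruct-transform-average (RTA): one
OSEM image per respiratory bin, warped to end-expiration, then averaged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .linops import WarpOp
from .motion import BinAssignment
from .mr_recon import DeformationFieldSet, ReconVolume
from .phantom import MotionModel, Phantom, warp_volume


# --------------------------------------------------------------------------
# geometry and projector
# --------------------------------------------------------------------------

@dataclass
class PETGeometry:
    """Stack-of-2D parallel-beam geometry.

    ``n_angles`` views over 180 deg; radial bins spaced ``rad_spacing_mm``
    centred on the slice; slices along the volume's z axis.
    """

    n_angles: int = 96
    n_rad: int = 64
    rad_spacing_mm: float = 2.0
    voxel_mm: float = 2.0
    psf_fwhm_mm: float = 4.5

    @property
    def angles(self) -> np.ndarray:
        return np.arange(self.n_angles) * np.pi / self.n_angles

    def psf_sigma_bins(self, psf_fwhm_mm: float | None = None) -> float:
        f = self.psf_fwhm_mm if psf_fwhm_mm is None else psf_fwhm_mm
        return f / 2.3548 / self.rad_spacing_mm


def build_projector(geom: PETGeometry, shape_xy: tuple[int, int]
                    ) -> sparse.csr_matrix:
    """Sparse (n_angles * n_rad, nx * ny) line-integral matrix (mm units).

    Rays step one voxel at a time; bilinear weights scaled by the step
    length give length-weighted integrals, so ``exp(-A @ mu)`` are the
    attenuation factors for ``mu`` in 1/mm.
    """
    if geom.n_angles < 2:
        raise ValueError("need at least 2 projection angles")
    nx, ny = shape_xy
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    rad = (np.arange(geom.n_rad) - (geom.n_rad - 1) / 2.0) * \
        geom.rad_spacing_mm / geom.voxel_mm          # voxel units
    half_diag = 0.5 * np.hypot(nx, ny) + 1
    t = np.arange(-half_diag, half_diag, 1.0)        # voxel-length steps

    rows, cols, vals = [], [], []
    for ia, ang in enumerate(geom.angles):
        d = np.array([np.cos(ang), np.sin(ang)])
        n = np.array([-np.sin(ang), np.cos(ang)])
        # sample points for all (radial, t) at once
        px = cx + rad[:, None] * n[0] + t[None, :] * d[0]
        py = cy + rad[:, None] * n[1] + t[None, :] * d[1]
        x0 = np.floor(px).astype(np.int64)
        y0 = np.floor(py).astype(np.int64)
        fx = px - x0
        fy = py - y0
        for ox, oy in ((0, 0), (0, 1), (1, 0), (1, 1)):
            xi = x0 + ox
            yi = y0 + oy
            w = (fx if ox else 1 - fx) * (fy if oy else 1 - fy)
            valid = (xi >= 0) & (xi < nx) & (yi >= 0) & (yi < ny) & (w > 0)
            r_idx, _ = np.nonzero(valid)
            rows.append(ia * geom.n_rad + r_idx)
            cols.append(xi[valid] * ny + yi[valid])
            vals.append(w[valid] * geom.voxel_mm)
    A = sparse.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(geom.n_angles * geom.n_rad, nx * ny),
    )
    return A.tocsr()


class Projector:
    """Matched forward/back-projector pair for a volume shape."""

    def __init__(self, geom: PETGeometry, shape: tuple[int, int, int]):
        self.geom = geom
        self.shape = shape
        self.A = build_projector(geom, shape[:2])
        self.AT = self.A.T.tocsr()
        self._sub_cache: dict = {}

    def _subset_ops(self, ang_idx: np.ndarray):
        key = (int(ang_idx[0]), len(ang_idx))
        if key not in self._sub_cache:
            rows = (ang_idx[:, None] * self.geom.n_rad
                    + np.arange(self.geom.n_rad)[None, :]).ravel()
            A_s = self.A[rows]
            self._sub_cache[key] = (A_s, A_s.T.tocsr())
        return self._sub_cache[key]

    def forward_sub(self, vol: np.ndarray, ang_idx: np.ndarray,
                    psf_fwhm_mm: float | None = 0.0) -> np.ndarray:
        """Subset forward projection: (n_slices, len(ang_idx), n_rad)."""
        A_s, _ = self._subset_ops(ang_idx)
        nx, ny, nz = self.shape
        s = (A_s @ vol.reshape(nx * ny, nz)).T.reshape(
            nz, len(ang_idx), self.geom.n_rad)
        return self._blur(s, psf_fwhm_mm)

    def adjoint_sub(self, sino_sub: np.ndarray, ang_idx: np.ndarray,
                    psf_fwhm_mm: float | None = 0.0) -> np.ndarray:
        _, AT_s = self._subset_ops(ang_idx)
        nx, ny, nz = self.shape
        s = self._blur(sino_sub, psf_fwhm_mm)
        return (AT_s @ s.reshape(nz, -1).T).reshape(nx, ny, nz)

    def _blur(self, sino: np.ndarray, psf_fwhm_mm: float | None) -> np.ndarray:
        sig = self.geom.psf_sigma_bins(psf_fwhm_mm)
        if sig <= 0:
            return sino
        return ndimage.gaussian_filter1d(sino, sig, axis=-1, mode="constant")

    def forward(self, vol: np.ndarray, psf_fwhm_mm: float | None = 0.0
                ) -> np.ndarray:
        """Volume (nx, ny, nz) -> sinogram (n_slices, n_angles, n_rad)."""
        nx, ny, nz = self.shape
        flat = vol.reshape(nx * ny, nz)
        s = (self.A @ flat).T.reshape(nz, self.geom.n_angles, self.geom.n_rad)
        return self._blur(s, psf_fwhm_mm)

    def adjoint(self, sino: np.ndarray, psf_fwhm_mm: float | None = 0.0
                ) -> np.ndarray:
        """Exact transpose of ``forward`` (Gaussian blur is self-adjoint)."""
        nx, ny, nz = self.shape
        s = self._blur(sino, psf_fwhm_mm)
        flat = self.AT @ s.reshape(nz, -1).T
        return flat.reshape(nx, ny, nz)


def project(volume: np.ndarray, geom: PETGeometry,
            psf_fwhm_mm: float = 0.0) -> np.ndarray:
    """One-shot slice-wise line integrals of ``volume``."""
    return Projector(geom, volume.shape).forward(volume, psf_fwhm_mm)


# --------------------------------------------------------------------------
# containers
# --------------------------------------------------------------------------

@dataclass
class SinogramSet:
    counts: np.ndarray               # (n_bins, n_slices, n_angles, n_rad) int
    att: np.ndarray                  # attenuation factors, same shape
    time_fraction: np.ndarray        # (n_bins,)
    geom: PETGeometry
    seed: int
    total_counts: float

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def summed(self) -> np.ndarray:
        """Un-binned sinogram (for the uncorrected comparator)."""
        return self.counts.sum(axis=0)


@dataclass
class MuMapSet:
    reference: np.ndarray
    per_bin: np.ndarray              # (n_bins, nx, ny, nz)
    voxel_mm: float


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

def simulate_pet(phantom: Phantom, model: MotionModel, bins: BinAssignment,
                 total_counts: float, geom: PETGeometry, seed: int = 0,
                 psf_in_simulation: bool = True
                 ) -> tuple[SinogramSet, MuMapSet]:
    """Simulate per-bin emission sinograms through the moving phantom.

    For each respiratory bin, activity and attenuation are warped to the
    bin-centre state relative to the reference bin (ground-truth motion
    model), attenuation factors ``exp(-int mu dl)`` are applied to the
    activity line integrals, and the mean sinogram is normalised so the
    bin's expected counts equal ``time_fraction x total_counts`` before
    Poisson sampling.  Rejected beats contribute no counts (their time
    fraction is lost, as in gated list-mode selection).
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    rng = np.random.default_rng(seed)
    proj = Projector(geom, phantom.shape)
    s = phantom.voxel_size[0]
    ref = bins.reference_bin

    n_total = bins.n_beats
    sinos, atts, mus, fracs = [], [], [], []
    for b in range(bins.n_bins):
        frac = bins.members(b).size / n_total
        dfh = bins.fh_centers[b] - bins.fh_centers[ref]
        drl = bins.rl_centers[b] - bins.rl_centers[ref]
        if dfh == 0.0 and drl == 0.0:
            act_b, mu_b = phantom.activity_volume, phantom.mu_map
        else:
            fld = model.displacement_field(dfh, drl, phantom.shape, s)
            act_b = warp_volume(phantom.activity_volume, fld, s)
            mu_b = warp_volume(phantom.mu_map, fld, s)
        att_b = np.exp(-proj.forward(mu_b, psf_fwhm_mm=0.0))
        mean_shape = att_b * proj.forward(
            act_b, psf_fwhm_mm=None if psf_in_simulation else 0.0)
        tot = mean_shape.sum()
        mean = (frac * total_counts / tot) * mean_shape if tot > 0 else mean_shape
        sinos.append(rng.poisson(mean))
        atts.append(att_b)
        mus.append(mu_b)
        fracs.append(frac)

    return (
        SinogramSet(counts=np.stack(sinos), att=np.stack(atts),
                    time_fraction=np.array(fracs), geom=geom, seed=seed,
                    total_counts=total_counts),
        MuMapSet(reference=phantom.mu_map, per_bin=np.stack(mus), voxel_mm=s),
    )


def warp_mumap(mu: np.ndarray, fields: DeformationFieldSet) -> MuMapSet:
    """Move the reference attenuation map to each respiratory position using
    the (estimated) bin-to-reference fields; the reference bin is untouched."""
    per_bin = []
    for b in range(fields.n_bins):
        if b == fields.reference_bin:
            per_bin.append(mu.copy())
        else:
            op = WarpOp(fields.fields_mm[b] / fields.voxel_mm)
            per_bin.append(np.maximum(op.forward(mu), 0.0))
    return MuMapSet(reference=mu, per_bin=np.stack(per_bin),
                    voxel_mm=fields.voxel_mm)


# --------------------------------------------------------------------------
# OSEM
# --------------------------------------------------------------------------

def osem(sino: np.ndarray, att: np.ndarray, geom: PETGeometry,
         shape: tuple[int, int, int] | None = None,
         n_iter: int = 3, n_subsets: int = 21,
         psf_fwhm_mm: float | None = None,
         projector: Projector | None = None) -> ReconVolume:
    """Attenuation-corrected ordered-subsets EM reconstruction of one bin.

    The system model is ``y = att * PSF(P x)``; angles are partitioned
    round-robin into ``n_subsets`` subsets (reduced with a warning when
    fewer angles are available); the image starts uniform positive and
    multiplicative updates keep it non-negative, with zero-sensitivity
    voxels masked.
    """
    if np.any(sino < 0):
        raise ValueError("sinogram must be non-negative")
    if projector is None:
        if shape is None:
            raise ValueError("need shape or projector")
        projector = Projector(geom, shape)
    shape = projector.shape
    if n_subsets > geom.n_angles:
        warnings.warn(f"reducing subsets {n_subsets} -> {geom.n_angles}",
                      stacklevel=2)
        n_subsets = geom.n_angles
    psf = geom.psf_fwhm_mm if psf_fwhm_mm is None else psf_fwhm_mm

    subsets = [np.arange(s, geom.n_angles, n_subsets) for s in range(n_subsets)]
    # per-subset sensitivity images, computed once
    sens_imgs = [projector.adjoint_sub(att[:, ang_idx, :], ang_idx, psf)
                 for ang_idx in subsets]
    x = np.ones(shape)
    for _ in range(n_iter):
        for ang_idx, sens in zip(subsets, sens_imgs):
            fp = projector.forward_sub(x, ang_idx, psf_fwhm_mm=psf)
            att_s = att[:, ang_idx, :]
            y_s = sino[:, ang_idx, :]
            est = att_s * fp
            ratio = np.divide(y_s, est, out=np.zeros_like(est), where=est > 0)
            back = projector.adjoint_sub(att_s * ratio, ang_idx, psf)
            upd = np.divide(back, sens, out=np.zeros_like(back),
                            where=sens > 1e-12 * sens.max())
            x = x * upd
    return ReconVolume(data=x.astype(complex), voxel_mm=geom.voxel_mm,
                       provenance="PET-OSEM")


# --------------------------------------------------------------------------
# reconstruct-transform-average
# --------------------------------------------------------------------------

def invert_field(field_mm: np.ndarray, voxel: float, n_iter: int = 15,
                 tol_vox: float = 0.1) -> np.ndarray:
    """Fixed-point inverse of a pull field: h with h(v) = -g(v + h(v))."""
    g_vox = field_mm / voxel
    h = -g_vox.copy()
    for _ in range(n_iter):
        samp = np.stack([WarpOp(h).forward(g_vox[c]) for c in range(3)])
        h_new = -samp
        if np.max(np.abs(h_new - h)) < tol_vox:
            h = h_new
            break
        h = h_new
    return h * voxel


def rta_combine(bin_recons: list[ReconVolume],
                fields: DeformationFieldSet,
                time_fraction: np.ndarray | None = None) -> ReconVolume:
    """Warp every bin reconstruction to the reference position and average.

    The reference->bin pull fields are inverted by fixed-point iteration to
    obtain the bin->reference transforms.  Bins are averaged with equal
    weights (they hold equal amounts of data); when ``time_fraction`` is
    given, each bin image is first divided by its acquisition-time fraction
    so the result is a count-rate image comparable across gating schemes.
    """
    if len(bin_recons) != fields.n_bins:
        raise ValueError("one reconstruction per bin is required")
    voxel = fields.voxel_mm
    out = np.zeros(bin_recons[0].data.shape)
    for b, rec in enumerate(bin_recons):
        img = rec.magnitude
        if time_fraction is not None:
            img = img / max(time_fraction[b], 1e-12)
        if b == fields.reference_bin or not np.any(fields.fields_mm[b]):
            out += img
        else:
            h = invert_field(fields.fields_mm[b], voxel)
            out += WarpOp(h / voxel).forward(img)
    out /= len(bin_recons)
    return ReconVolume(data=out.astype(complex), voxel_mm=voxel,
                       provenance="PET-MC")


def pet_nmc(sinos: SinogramSet, mu_ref: np.ndarray,
            shape: tuple[int, int, int], n_iter: int = 3, n_subsets: int = 21,
            psf_fwhm_mm: float | None = None,
            projector: Projector | None = None) -> ReconVolume:
    """Uncorrected comparator: OSEM on the un-binned sum sinogram with the
    reference (end-expiration) attenuation map."""
    proj = projector or Projector(sinos.geom, shape)
    att = np.exp(-proj.forward(mu_ref, psf_fwhm_mm=0.0))
    rec = osem(sinos.summed(), att, sinos.geom, n_iter=n_iter,
               n_subsets=n_subsets, psf_fwhm_mm=psf_fwhm_mm, projector=proj)
    # count-rate image: normalise by the accepted acquisition-time fraction
    rec.data = rec.data / max(sinos.time_fraction.sum(), 1e-12)
    rec.provenance = "PET-NMC"
    return rec


def pet_mc(sinos: SinogramSet, mumaps: MuMapSet, fields: DeformationFieldSet,
           shape: tuple[int, int, int], n_iter: int = 3, n_subsets: int = 21,
           psf_fwhm_mm: float | None = None,
           projector: Projector | None = None) -> ReconVolume:
    """Motion-corrected PET: per-bin OSEM with that bin's attenuation map,
    then reconstruct-transform-average to the reference position."""
    proj = projector or Projector(sinos.geom, shape)
    recons = []
    for b in range(sinos.n_bins):
        att_b = np.exp(-proj.forward(mumaps.per_bin[b], psf_fwhm_mm=0.0))
        recons.append(osem(sinos.counts[b], att_b, sinos.geom, n_iter=n_iter,
                           n_subsets=n_subsets, psf_fwhm_mm=psf_fwhm_mm,
                           projector=proj))
    rec = rta_combine(recons, fields, time_fraction=sinos.time_fraction)
    return rec
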