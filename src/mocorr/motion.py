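"""Beat-wise respiratory motion estimation and binning.

Step 1: rigid registration of an apex template between the reference iNAV
and every other iNAV gives per-beat FH/RL translation.  Step 2: beats are
sorted into equal-count respiratory bins from end-expiration to
end-inspiration, deep breaths are rejected as outliers, and every CMRA
interleaf is corrected to its bin centre by a k-space phase shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from skimage.feature import match_template

from .acquisition import INavSeries, KSpaceData
from .linops import freq_index

REJECTED = -1


@dataclass
class MotionTable:
    """Estimated per-beat displacement (mm) relative to the reference beat."""

    fh_mm: np.ndarray
    rl_mm: np.ndarray
    score: np.ndarray            # peak normalised cross-correlation per beat
    reference_beat: int

    @property
    def n_beats(self) -> int:
        return len(self.fh_mm)


@dataclass
class OutlierRule:
    """Deep-breath rejection rule.

    ``iqr``: reject beats whose FH lies more than ``k`` interquartile ranges
    beyond the quartile on the inspiratory side (away from end-expiration).
    ``abs``: reject |FH - end-expiration mode| > ``threshold_mm``.
    ``none``: keep everything.
    """

    method: str = "iqr"
    k: float = 1.5
    threshold_mm: float = 15.0


@dataclass
class BinAssignment:
    n_bins: int
    labels: np.ndarray           # per-beat bin id, REJECTED = -1
    fh_centers: np.ndarray       # (n_bins,) mm, index 0 = end-expiration
    rl_centers: np.ndarray
    weights: np.ndarray          # (n_beats, n_bins) soft weights, rows sum to 1
    reference_bin: int = 0

    @property
    def n_beats(self) -> int:
        return len(self.labels)

    def members(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.labels == b)

    @property
    def accepted(self) -> np.ndarray:
        return self.labels != REJECTED


# --------------------------------------------------------------------------
# step 1: template registration
# --------------------------------------------------------------------------

def default_template(inavs: INavSeries, lv_geometry) -> tuple[int, int, int, int]:
    """Rectangular template (x0, z0, wx, wz) in display pixels covering the
    apex of the heart, derived from the phantom's LV geometry."""
    p = inavs.display_pixel_mm
    cx = lv_geometry.center_xy[0] / p
    az = lv_geometry.apex_z / p
    r = lv_geometry.r_outer / p
    x0 = int(round(cx - 1.2 * r))
    z0 = int(round(az - 1.4 * r))
    w = int(round(2.4 * r))
    h = int(round(2.2 * r))
    return x0, z0, w, h


def _parabolic_offset(c_m: float, c0: float, c_p: float) -> float:
    denom = c_m - 2.0 * c0 + c_p
    if denom >= 0 or abs(denom) < 1e-15:
        return 0.0
    off = 0.5 * (c_m - c_p) / denom
    return float(np.clip(off, -0.5, 0.5))


def estimate_translation(inavs: INavSeries,
                         template: tuple[int, int, int, int],
                         reference: int = 0,
                         score_threshold: float = 0.5) -> MotionTable:
    """Estimate per-beat (FH, RL) translation by template matching.

    The template region is cut from the reference iNAV and located in every
    iNAV by normalised cross-correlation; the correlation peak is refined to
    sub-pixel precision by a separable parabolic fit.  Displacements are in
    mm on the display grid and are zero at the reference beat by
    construction.
    """
    x0, z0, wx, wz = template
    ref_img = inavs.images[reference]
    if x0 < 0 or z0 < 0 or x0 + wx > ref_img.shape[0] or z0 + wz > ref_img.shape[1]:
        raise ValueError("template outside the iNAV field of view")
    tpl = ref_img[x0:x0 + wx, z0:z0 + wz]
    if tpl.std() == 0:
        raise ValueError("flat template: cannot register")

    p = inavs.display_pixel_mm
    n = inavs.n_beats
    fh = np.zeros(n)
    rl = np.zeros(n)
    score = np.zeros(n)
    pad = max(8, int(round(24.0 / p)))   # allow large (deep-breath) shifts
    for b in range(n):
        img = np.pad(inavs.images[b], pad, mode="edge")
        cc = match_template(img, tpl, pad_input=False)
        ix, iz = np.unravel_index(np.argmax(cc), cc.shape)
        score[b] = cc[ix, iz]
        dx = ix - x0 - pad
        dz = iz - z0 - pad
        # sub-pixel refinement (negated correlation: parabola through maximum)
        if 0 < ix < cc.shape[0] - 1:
            dx += _parabolic_offset(-cc[ix - 1, iz], -cc[ix, iz], -cc[ix + 1, iz])
        if 0 < iz < cc.shape[1] - 1:
            dz += _parabolic_offset(-cc[ix, iz - 1], -cc[ix, iz], -cc[ix, iz + 1])
        rl[b] = dx * p
        fh[b] = dz * p
    fh -= fh[reference]
    rl -= rl[reference]
    return MotionTable(fh_mm=fh, rl_mm=rl, score=score, reference_beat=reference)


# --------------------------------------------------------------------------
# step 2: equal-count binning with outlier rejection
# --------------------------------------------------------------------------

def _end_expiration_value(fh: np.ndarray) -> float:
    """End-expiratory FH level: the dense (most-frequent) end of the trace.

    Breathing spends most of the cycle near end-expiration, so the quartile
    spreads identify the dense side robustly; the level itself is the 2.5th
    or 97.5th percentile on that side.
    """
    q1, q2, q3 = np.percentile(fh, [25, 50, 75])
    if (q2 - q1) >= (q3 - q2):       # long tail below -> end-expiration above
        return float(np.percentile(fh, 97.5))
    return float(np.percentile(fh, 2.5))


def assign_bins(motion: MotionTable, n_bins: int = 4,
                outlier_rule: OutlierRule | None = None) -> BinAssignment:
    """Split accepted beats into ``n_bins`` equal-count respiratory windows.

    Beats violating the deep-breath rule are REJECTED; the rest are sorted
    by FH distance from end-expiration and cut into quantile groups whose
    sizes differ by at most one.  Bin 0 is the end-expiratory (reference)
    bin; bin centres are the median FH/RL of the members.
    """
    rule = outlier_rule or OutlierRule()
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    fh = motion.fh_mm
    n = motion.n_beats

    mode = _end_expiration_value(fh)
    keep = np.ones(n, dtype=bool)
    if rule.method == "iqr":
        # two-sided fence; deep breaths sit far beyond the inspiratory
        # quartile while the end-expiratory side has no tail to lose
        q1, q3 = np.percentile(fh, [25, 75])
        iqr = q3 - q1
        keep = (fh >= q1 - rule.k * iqr) & (fh <= q3 + rule.k * iqr)
    elif rule.method == "abs":
        keep = np.abs(fh - mode) <= rule.threshold_mm
    elif rule.method != "none":
        raise ValueError(f"unknown outlier rule {rule.method!r}")

    acc = np.flatnonzero(keep)
    if len(acc) < n_bins:
        raise ValueError("not enough accepted beats for the requested bins")

    # order accepted beats from end-expiration toward end-inspiration
    dist = np.abs(fh[acc] - mode)
    order = acc[np.argsort(dist, kind="stable")]
    groups = np.array_split(order, n_bins)

    labels = np.full(n, REJECTED, dtype=int)
    fh_c = np.zeros(n_bins)
    rl_c = np.zeros(n_bins)
    for b, g in enumerate(groups):
        labels[g] = b
        fh_c[b] = np.median(fh[g])
        rl_c[b] = np.median(motion.rl_mm[g])

    weights = np.zeros((n, n_bins))
    weights[acc, labels[acc]] = 1.0
    return BinAssignment(n_bins=n_bins, labels=labels, fh_centers=fh_c,
                         rl_centers=rl_c, weights=weights, reference_bin=0)


def soft_weights(motion: MotionTable, bins: BinAssignment,
                 width: float | None = None) -> BinAssignment:
    """Replace hard bin membership by Gaussian soft-gating weights.

    Each accepted beat receives ``exp(-(fh - centre)^2 / (2 width^2))`` for
    every bin, renormalised to sum to one over bins.  ``width=None`` uses
    half the mean bin-centre spacing; ``width -> 0`` recovers hard binning.
    """
    if width is None:
        if bins.n_bins > 1:
            width = 0.5 * float(np.mean(np.abs(np.diff(bins.fh_centers))))
        else:
            width = 0.0
    if width < 0:
        raise ValueError("width must be >= 0")
    if width == 0.0 or bins.n_bins == 1:
        return bins
    w = np.exp(-0.5 * ((motion.fh_mm[:, None] - bins.fh_centers[None, :])
                       / width) ** 2)
    w[~bins.accepted] = 0.0
    norm = w.sum(axis=1, keepdims=True)
    w = np.divide(w, norm, out=np.zeros_like(w), where=norm > 0)
    # beats so far from every centre that the kernel underflows keep their
    # hard assignment
    dead = bins.accepted & (norm[:, 0] == 0)
    w[dead, bins.labels[dead]] = 1.0
    return replace(bins, weights=w)


# --------------------------------------------------------------------------
# translational k-space correction
# --------------------------------------------------------------------------

def _line_phases(kspace: KSpaceData, dfh: np.ndarray, drl: np.ndarray):
    """Per-interleaf, per-line phase factors shifting each beat's object by
    (drl, dfh) mm (the Fourier shift theorem on the centred grid)."""
    n1, n2 = kspace.traj.matrix_yz
    fov1 = n1 * kspace.voxel_mm
    fov2 = n2 * kspace.voxel_mm
    f1 = freq_index(n1)
    f2 = freq_index(n2)
    phases = []
    for i, arm in enumerate(kspace.traj.interleaves):
        k1 = f1[arm[:, 0]]
        k2 = f2[arm[:, 1]]
        ph = np.exp(-2j * np.pi * (k1 * drl[i] / fov1 + k2 * dfh[i] / fov2))
        full = np.ones(kspace.traj.lines_per_interleaf, dtype=complex)
        full[:len(arm)] = ph
        phases.append(full)
    return np.stack(phases)


def correct_translational(kspace: KSpaceData, motion: MotionTable,
                          bins: BinAssignment) -> KSpaceData:
    """Correct every interleaf to its bin centre by a k-space phase shift.

    Each beat's samples are multiplied by the linear phase that translates
    the object by (centre - beat) mm in RL and FH; rejected beats' data are
    dropped (marked not accepted).
    """
    n_int = kspace.traj.n_interleaves
    if motion.n_beats < n_int or bins.n_beats < n_int:
        raise ValueError("motion table does not cover every interleaf")
    lab = bins.labels[:n_int]
    acc = lab != REJECTED
    dfh = np.zeros(n_int)
    drl = np.zeros(n_int)
    dfh[acc] = bins.fh_centers[lab[acc]] - motion.fh_mm[:n_int][acc]
    drl[acc] = bins.rl_centers[lab[acc]] - motion.rl_mm[:n_int][acc]
    phases = _line_phases(kspace, dfh, drl)
    data = kspace.data * phases[None, :, :, None]
    return replace(kspace, data=data, accepted=acc.copy())
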