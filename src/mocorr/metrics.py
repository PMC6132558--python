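"""Image-quality metrics: vessel length & sharpness, AHA 17-segment maps.

Vessel sharpness follows the centreline-normalised definition: intensity
profiles are drawn perpendicular to the local vessel direction, the maximum
absolute spatial derivative at each edge is scaled by one voxel and divided
by the centreline intensity, so an ideal one-voxel step from lumen to zero
background scores 100%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import Centerline, LVGeometry, _aha_angle


@dataclass
class VesselMetrics:
    vessel_id: str
    visible_length_mm: float
    sharpness_pct: float
    per_point_sharpness: np.ndarray
    per_point_contrast: np.ndarray


@dataclass
class PolarMap:
    """AHA 17-segment summary: 1-6 basal, 7-12 mid, 13-16 apical, 17 apex."""

    values: np.ndarray               # (17,)
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (17,):
            raise ValueError("a polar map has exactly 17 segment values")


def _volume_of(v) -> np.ndarray:
    return np.abs(v.data) if hasattr(v, "data") else np.abs(np.asarray(v))


def _profiles(volume: np.ndarray, centerline: Centerline, voxel: float,
              profile_len_mm: float, step_vox: float = 0.25):
    """Sample two perpendicular intensity profiles at each centreline point.

    Returns (centre intensities, profiles[n_pts, 2, n_samp], step in voxels).
    The perpendicular frame is built deterministically from the local
    tangent so axis-aligned tubes get axis-aligned profiles.
    """
    pts = centerline.points_mm / voxel - 0.5          # voxel-centre coords
    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)

    n_half = int(round(profile_len_mm / 2.0 / (step_vox * voxel)))
    offs = (np.arange(-n_half, n_half + 1)) * step_vox

    prof = np.empty((len(pts), 2, len(offs)))
    for a_idx, axis_ref in enumerate((np.array([1.0, 0, 0]),
                                      np.array([0, 1.0, 0]))):
        perp = axis_ref[None, :] - (tang * (tang @ axis_ref)[:, None])
        bad = np.linalg.norm(perp, axis=1) < 1e-6
        perp[bad] = np.array([0, 0, 1.0]) - (
            tang[bad] * (tang[bad] @ np.array([0, 0, 1.0]))[:, None])
        perp /= np.maximum(np.linalg.norm(perp, axis=1, keepdims=True), 1e-12)
        coords = pts[:, :, None] + perp[:, :, None] * offs[None, None, :]
        prof[:, a_idx, :] = ndimage.map_coordinates(
            volume, coords.transpose(1, 0, 2), order=1, mode="nearest")
    centre = ndimage.map_coordinates(volume, pts.T, order=1, mode="nearest")
    return centre, prof, step_vox


def vessel_sharpness(volume, centerline: Centerline, voxel_mm: float,
                     profile_len_mm: float = 16.0) -> VesselMetrics:
    """Normalised vessel sharpness (%) averaged over both edges and all
    centreline points."""
    vol = _volume_of(volume)
    centre, prof, step = _profiles(vol, centerline, voxel_mm, profile_len_mm)
    if np.any(centre <= 0):
        raise ValueError("zero centreline intensity")
    # central differences on the 0.25-voxel grid -> derivative per voxel
    deriv = np.gradient(prof, step, axis=-1)
    mid = prof.shape[-1] // 2
    left = np.max(np.abs(deriv[:, :, :mid]), axis=-1)
    right = np.max(np.abs(deriv[:, :, mid:]), axis=-1)
    per_edge = np.stack([left, right], axis=-1)      # (n_pts, 2 dirs, 2 edges)
    per_point = per_edge.mean(axis=(1, 2)) / centre * 100.0
    return VesselMetrics(
        vessel_id=centerline.vessel_id,
        visible_length_mm=float(centerline.arc_length_mm[-1]),
        sharpness_pct=float(per_point.mean()),
        per_point_sharpness=per_point,
        per_point_contrast=centre,
    )


@dataclass
class VisibilityRule:
    contrast_ratio: float = 1.5
    window: int = 3                  # consecutive points allowed to dip
    background_offset_mm: float = 4.0


def vessel_length(volume, centerline: Centerline, voxel_mm: float,
                  rule: VisibilityRule | None = None) -> float:
    """Arc length (mm) of the longest contiguous visible run from the vessel
    origin.

    A point is visible when the centreline intensity exceeds
    ``contrast_ratio`` times the local background (median intensity on a
    ring ``radius + background_offset`` from the axis); dips shorter than
    ``window`` points are bridged.
    """
    rule = rule or VisibilityRule()
    vol = _volume_of(volume)
    pts = centerline.points_mm / voxel_mm - 0.5
    centre = ndimage.map_coordinates(vol, pts.T, order=1, mode="nearest")

    tang = np.gradient(pts, axis=0)
    tang /= np.maximum(np.linalg.norm(tang, axis=1, keepdims=True), 1e-12)
    r_bg = (centerline.radius_mm + rule.background_offset_mm) / voxel_mm
    angles = np.linspace(0, 2 * np.pi, 8, endpoint=False)
    ref = np.array([1.0, 0, 0])
    perp1 = ref[None, :] - tang * (tang @ ref)[:, None]
    bad = np.linalg.norm(perp1, axis=1) < 1e-6
    perp1[bad] = [0, 0, 1.0]
    perp1 /= np.maximum(np.linalg.norm(perp1, axis=1, keepdims=True), 1e-12)
    perp2 = np.cross(tang, perp1)
    ring = (pts[:, :, None]
            + r_bg[:, None, None] * (perp1[:, :, None] * np.cos(angles)
                                     + perp2[:, :, None] * np.sin(angles)))
    bg = ndimage.map_coordinates(vol, ring.transpose(1, 0, 2), order=1,
                                 mode="nearest")
    bg_med = np.median(bg, axis=-1)
    visible = centre > rule.contrast_ratio * np.maximum(bg_med, 1e-9)

    # bridge dips shorter than the window, then take the run from the origin
    vis = visible.copy()
    i = 0
    n = len(vis)
    while i < n:
        if not vis[i]:
            j = i
            while j < n and not vis[j]:
                j += 1
            if j - i < rule.window and i > 0 and j < n:
                vis[i:j] = True
            i = j
        else:
            i += 1
    arc = centerline.arc_length_mm
    end = int(np.argmin(vis)) if not vis.all() else n - 1
    if not vis[0]:
        return 0.0
    return float(arc[end] if not vis.all() else arc[-1])


# --------------------------------------------------------------------------
# AHA 17-segment polar map
# --------------------------------------------------------------------------

def _segment_labels(shape, voxel_mm: float, lv: LVGeometry,
                    myo_mask: np.ndarray) -> np.ndarray:
    """Per-voxel AHA segment id (1..17, 0 outside the myocardial mask)."""
    nx, ny, nz = shape
    xx, yy, zz = np.meshgrid((np.arange(nx) + 0.5) * voxel_mm,
                             (np.arange(ny) + 0.5) * voxel_mm,
                             (np.arange(nz) + 0.5) * voxel_mm, indexing="ij")
    dx = xx - lv.center_xy[0]
    dy = yy - lv.center_xy[1]
    ang = _aha_angle(dx, dy)                  # 0 = anterior, ccw from apex
    zeta = (zz - lv.apex_z) / (lv.base_z - lv.apex_z)

    lab = np.zeros(shape, dtype=int)
    six = ((ang + np.pi / 6) % (2 * np.pi) / (np.pi / 3)).astype(int)  # 0..5
    four = ((ang + np.pi / 4) % (2 * np.pi) / (np.pi / 2)).astype(int)  # 0..3
    basal = zeta >= 2.0 / 3.0
    mid = (zeta >= 1.0 / 3.0) & (zeta < 2.0 / 3.0)
    apical = (zeta >= 0.0) & (zeta < 1.0 / 3.0)
    apex = zeta < 0.0                         # hemispherical cap
    lab[basal] = 1 + six[basal]
    lab[mid] = 7 + six[mid]
    lab[apical] = 13 + four[apical]
    lab[apex] = 17
    lab[~myo_mask] = 0
    return lab


def polar_map_17(volume, lv: LVGeometry, myo_mask: np.ndarray,
                 voxel_mm: float) -> PolarMap:
    """Mean image intensity per AHA segment of the LV myocardium.

    Basal and mid thirds of the long axis carry 6 circumferential sectors
    each (zero angle at the anterior wall, counterclockwise seen from the
    apex), the apical third 4 sectors, and the apex cap is segment 17.
    Empty sectors are flagged as NaN.
    """
    vol = _volume_of(volume)
    lab = _segment_labels(vol.shape, voxel_mm, lv, myo_mask)
    vals = np.full(17, np.nan)
    for s in range(1, 18):
        m = lab == s
        if m.any():
            vals[s - 1] = vol[m].mean()
    return PolarMap(values=vals)


def segment_masks(shape, voxel_mm: float, lv: LVGeometry,
                  myo_mask: np.ndarray) -> np.ndarray:
    """Per-voxel segment labels (public helper for tests and plotting)."""
    return _segment_labels(shape, voxel_mm, lv, myo_mask)


def relative_increase(mc: PolarMap, nmc: PolarMap) -> PolarMap:
    """Per-segment percent signal change of MC over NMC:
    ``100 * (MC - NMC) / NMC``; segments with zero NMC signal are NaN."""
    out = np.full(17, np.nan)
    ok = (nmc.values != 0) & ~np.isnan(nmc.values) & ~np.isnan(mc.values)
    out[ok] = 100.0 * (mc.values[ok] - nmc.values[ok]) / nmc.values[ok]
    return PolarMap(values=out, normalized=True)
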