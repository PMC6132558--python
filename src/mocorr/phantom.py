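"""Digital thorax phantom with respiratory motion.

The phantom provides three co-registered volumes — an MR contrast volume
(bright arterial blood, suppressed myocardium/fat, as after T2-preparation
and fat saturation), an ``[18F]``-FDG activity volume (avid left-ventricular
myocardium, optional wedge-shaped viability defect) and a four-class 511 keV
attenuation map — together with ground-truth coronary centerlines and the
left-ventricular geometry needed for 17-segment analysis.

Axis convention: arrays are indexed ``(x, y, z)`` = (right–left,
anterior–posterior, foot–head), 0-based and voxel-centred; the coronal
plane is x–z and foot–head is positive toward the head.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage


# --------------------------------------------------------------------------
# breathing trace
# --------------------------------------------------------------------------

@dataclass
class BreathingTrace:
    """Per-heartbeat respiratory displacement of the heart.

    ``fh_mm`` is zero at end-expiration by convention and negative toward the
    feet during inspiration.  ``deep_breath_flag`` marks beats whose
    oscillatory excursion (drift removed) exceeds ``deep_breath_threshold``.
    """

    heartbeat_times: np.ndarray      # s
    fh_mm: np.ndarray
    rl_mm: np.ndarray
    deep_breath_flag: np.ndarray     # bool
    seed: int
    deep_breath_threshold: float = np.inf

    def __post_init__(self) -> None:
        n = len(self.heartbeat_times)
        if not (len(self.fh_mm) == len(self.rl_mm) == len(self.deep_breath_flag) == n):
            raise ValueError("trace arrays must have equal length")

    @property
    def n_beats(self) -> int:
        return len(self.fh_mm)


def simulate_breathing(
    n_beats: int,
    rr_interval: float = 1.0,
    amplitude: float = 10.0,
    period: float = 4.0,
    drift: float = 0.0,
    deep_breath_prob: float = 0.0,
    deep_breath_scale: float = 2.0,
    rl_fraction: float = 0.3,
    seed: int = 0,
    period_jitter: float = 0.08,
) -> BreathingTrace:
    """Simulate a pseudo-periodic foot–head breathing trace sampled at R-waves.

    The base waveform is ``-amplitude * sin(phase)**4``: the fourth power
    produces the prolonged end-expiratory plateau of tidal breathing, and the
    sign places inspiration toward the feet.  The breathing phase advances
    with a slowly varying period (fractional jitter ``period_jitter``), a
    linear baseline ``drift`` (mm/min) is added, and with probability
    ``deep_breath_prob`` a beat's oscillatory excursion is scaled by
    ``deep_breath_scale`` (a deep breath).

    Parameters are physical: ``rr_interval`` and ``period`` in seconds,
    ``amplitude`` in mm.  The trace is reproducible given ``seed``.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if rr_interval <= 0 or period <= 0:
        raise ValueError("rr_interval and period must be positive")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    if not 0.0 <= deep_breath_prob <= 1.0:
        raise ValueError("deep_breath_prob must be a probability")

    rng = np.random.default_rng(seed)
    t = np.arange(n_beats) * rr_interval

    # slowly-varying breathing period: smooth the per-beat jitter
    eps = rng.standard_normal(n_beats)
    if n_beats > 4:
        eps = ndimage.uniform_filter1d(eps, size=5, mode="nearest")
    dphase = (np.pi * rr_interval / period) * (1.0 + period_jitter * eps)
    phase = np.cumsum(dphase) - dphase[0]

    osc = amplitude * np.sin(phase) ** 4
    deep = rng.random(n_beats) < deep_breath_prob
    scale = np.where(deep, deep_breath_scale, 1.0)
    osc_scaled = osc * scale

    threshold = 1.05 * amplitude if amplitude > 0 else np.inf
    flags = osc_scaled > threshold

    fh = -osc_scaled + drift * t / 60.0
    rl = rl_fraction * fh
    return BreathingTrace(
        heartbeat_times=t,
        fh_mm=fh,
        rl_mm=rl,
        deep_breath_flag=flags,
        seed=seed,
        deep_breath_threshold=threshold,
    )


# --------------------------------------------------------------------------
# phantom geometry
# --------------------------------------------------------------------------

@dataclass
class LVGeometry:
    """Left-ventricular geometry in mm (world coordinates).

    The long axis is aligned with +z (foot–head); ``apex_z < base_z``.
    ``anterior`` is the in-plane unit vector pointing toward the chest wall,
    used as the zero-angle reference of the 17-segment model.
    """

    center_xy: tuple[float, float]
    base_z: float
    apex_z: float
    r_inner: float
    r_outer: float
    anterior: tuple[float, float] = (0.0, -1.0)


@dataclass
class DefectSpec:
    """Angular wedge viability defect.

    ``angle_deg`` is the wedge centre in the AHA circumferential convention
    (0 deg = anterior, increasing counterclockwise seen from the apex, i.e.
    anterior -> septal -> inferior -> lateral); ``transmurality`` is the
    residual activity fraction inside the wedge (0.2 keeps 20%).
    """

    angle_deg: float = 180.0          # inferior wall
    width_deg: float = 60.0
    transmurality: float = 0.2
    axial_range: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)  # mid third


@dataclass
class Centerline:
    vessel_id: str
    points_mm: np.ndarray            # (n, 3)
    radius_mm: np.ndarray            # (n,)

    @property
    def arc_length_mm(self) -> np.ndarray:
        d = np.linalg.norm(np.diff(self.points_mm, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(d)])


@dataclass
class StenosisSpec:
    vessel_id: str = "RCA"
    arc_length_mm: float = 40.0
    severity: float = 0.5            # radius at the centre = severity * nominal
    extent_mm: float = 6.0


@dataclass
class PhantomConfig:
    matrix: int = 64
    voxel_mm: float = 2.0
    n_vessels: int = 2
    vessel_radius_mm: float = 2.5
    defect: DefectSpec | None = None
    stenosis: StenosisSpec | None = None
    # tissue values (MR signal a.u., activity a.u., mu mm^-1 handled below)
    mr_blood: float = 1.0
    mr_myocardium: float = 0.25
    mr_liver: float = 0.35
    mr_soft: float = 0.2
    mr_fat: float = 0.1
    mr_lung: float = 0.05
    act_myocardium: float = 1.0
    act_blood: float = 0.12
    act_liver: float = 0.3
    act_soft: float = 0.05
    act_lung: float = 0.02


MU_AIR = 0.0
MU_LUNG = 0.0022
MU_SOFT = 0.0096
MU_BONE = 0.0120
MU_CLASSES = (MU_AIR, MU_LUNG, MU_SOFT, MU_BONE)


@dataclass
class Phantom:
    mr_volume: np.ndarray
    activity_volume: np.ndarray
    mu_map: np.ndarray
    voxel_size: tuple[float, float, float]
    centerlines: list[Centerline]
    lv_geometry: LVGeometry
    defect_spec: DefectSpec | None
    config: PhantomConfig = field(default=None, repr=False)  # type: ignore[assignment]
    myocardium_mask: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mr_volume.shape

    def world_grid(self):
        """Voxel-centre coordinates in mm, one 1-D array per axis."""
        return tuple(
            (np.arange(n) + 0.5) * s for n, s in zip(self.shape, self.voxel_size)
        )


def _ellipsoid(xx, yy, zz, center, semi):
    return (
        ((xx - center[0]) / semi[0]) ** 2
        + ((yy - center[1]) / semi[1]) ** 2
        + ((zz - center[2]) / semi[2]) ** 2
    ) <= 1.0


def _vessel_paths(cfg: PhantomConfig, heart_center, r_epi, base_z, apex_z):
    """Parametric epicardial vessel centerlines (mm).

    Two vessels by default: an RCA-like course descending in the right
    atrioventricular groove toward the inferior apex, and a LAD-like course
    descending along the anterior interventricular groove.
    """
    cx, cy, cz = heart_center
    t = np.linspace(0.0, 1.0, 161)
    paths = []

    # RCA-like: angle sweeps from anterior-right around the right side to
    # inferior while descending from base to apex level.
    ang = np.deg2rad(-40.0 + 200.0 * t)     # relative to anterior (-y), toward -x
    x = cx - r_epi * np.sin(ang)
    y = cy - r_epi * np.cos(ang) * 0.9
    z = base_z - (base_z - apex_z) * (0.05 + 0.9 * t)
    paths.append(("RCA", np.stack([x, y, z], axis=1)))

    if cfg.n_vessels >= 2:
        # LAD-like: stays anterior, gentle leftward drift, base -> apex.
        ang2 = np.deg2rad(25.0 * np.sin(np.pi * t) + 15.0 * t)
        x2 = cx + r_epi * np.sin(ang2)
        y2 = cy - r_epi * np.cos(ang2) * 0.95
        z2 = base_z - (base_z - apex_z) * (0.02 + 0.95 * t)
        paths.append(("LAD", np.stack([x2, y2, z2], axis=1)))
    return paths


def build_phantom(config: PhantomConfig | None = None) -> Phantom:
    """Construct the digital thorax phantom.

    The scene holds a torso ellipsoid with two lungs, a spine, a liver dome
    below the left lung, and a heart whose LV is a myocardial ring (activity
    bright) around a blood pool (MR bright), capped by a hemispherical apex.
    Coronary vessels are tubes of bright MR lumen on the epicardial surface;
    ground-truth centerlines are returned in mm.  The attenuation map is the
    four-class (air / lung / soft tissue / bone) 511 keV map.
    """
    cfg = config or PhantomConfig()
    n = cfg.matrix
    if n < 32:
        raise ValueError("matrix size must be >= 32")
    s = cfg.voxel_mm
    if cfg.vessel_radius_mm < s:
        raise ValueError("vessel radius must be >= 1 voxel")
    fov = n * s
    ax = (np.arange(n) + 0.5) * s
    xx, yy, zz = np.meshgrid(ax, ax, ax, indexing="ij")
    c = fov / 2.0

    mr = np.zeros((n, n, n))
    act = np.zeros((n, n, n))
    mu = np.zeros((n, n, n))

    torso = _ellipsoid(xx, yy, zz, (c, c, c), (0.46 * fov, 0.38 * fov, 0.52 * fov))
    mr[torso] = cfg.mr_soft
    act[torso] = cfg.act_soft
    mu[torso] = MU_SOFT

    # lungs: two ellipsoids in the upper half
    for sx in (-1.0, 1.0):
        lung = _ellipsoid(
            xx, yy, zz,
            (c + sx * 0.22 * fov, c, c + 0.12 * fov),
            (0.16 * fov, 0.24 * fov, 0.30 * fov),
        )
        mr[lung] = cfg.mr_lung
        act[lung] = cfg.act_lung
        mu[lung] = MU_LUNG

    # liver dome under the right lung (left of image for +x = left; keep +x side)
    liver = _ellipsoid(
        xx, yy, zz,
        (c - 0.18 * fov, c + 0.05 * fov, c - 0.22 * fov),
        (0.2 * fov, 0.22 * fov, 0.16 * fov),
    )
    mr[liver] = cfg.mr_liver
    act[liver] = cfg.act_liver
    mu[liver] = MU_SOFT

    # spine: posterior bone cylinder
    spine = ((xx - c) ** 2 + (yy - (c + 0.3 * fov)) ** 2) <= (0.05 * fov) ** 2
    spine &= torso
    mu[spine] = MU_BONE
    mr[spine] = cfg.mr_soft * 0.8

    # ---- heart ----
    hc = (c + 0.08 * fov, c - 0.08 * fov, c + 0.02 * fov)
    r_outer = 0.155 * fov
    r_inner = 0.085 * fov
    base_z = hc[2] + 0.16 * fov
    apex_z = hc[2] - 0.16 * fov

    # pericardial fat shell around the heart (dark MR background for vessels)
    peri = _ellipsoid(xx, yy, zz, hc, (r_outer + 8 * s / 2, r_outer + 8 * s / 2,
                                       (base_z - apex_z) / 2 + 8 * s / 2))
    mr[peri] = cfg.mr_fat
    act[peri] = cfg.act_soft
    mu[peri] = MU_SOFT

    rho = np.hypot(xx - hc[0], yy - hc[1])
    ring = (rho <= r_outer) & (rho >= r_inner) & (zz >= apex_z) & (zz <= base_z)
    # hemispherical apex cap below apex_z
    cap_r = np.sqrt(rho ** 2 + np.maximum(apex_z - zz, 0.0) ** 2)
    cap = (zz < apex_z) & (cap_r <= r_outer) & (cap_r >= r_inner)
    myo = ring | cap
    pool = ((rho < r_inner) & (zz >= apex_z) & (zz <= base_z)) | (
        (zz < apex_z) & (cap_r < r_inner)
    )

    mr[myo] = cfg.mr_myocardium
    act[myo] = cfg.act_myocardium
    mu[myo | pool] = MU_SOFT
    mr[pool] = cfg.mr_blood
    act[pool] = cfg.act_blood

    lv = LVGeometry(center_xy=(hc[0], hc[1]), base_z=base_z, apex_z=apex_z,
                    r_inner=r_inner, r_outer=r_outer)

    # wedge defect: reduce activity inside the angular wedge of the ring
    if cfg.defect is not None:
        d = cfg.defect
        ang = _aha_angle(xx - hc[0], yy - hc[1])
        dang = np.abs((ang - np.deg2rad(d.angle_deg) + np.pi) % (2 * np.pi) - np.pi)
        zeta = (zz - apex_z) / (base_z - apex_z)
        wedge = (
            myo
            & (dang <= np.deg2rad(d.width_deg) / 2.0)
            & (zeta >= d.axial_range[0])
            & (zeta < d.axial_range[1])
        )
        act[wedge] *= d.transmurality

    # ---- coronary vessels ----
    r_epi = r_outer + 2.0 * s
    centerlines = []
    for vid, pts in _vessel_paths(cfg, hc, r_epi, base_z, apex_z):
        radius = np.full(len(pts), cfg.vessel_radius_mm)
        if cfg.stenosis is not None and cfg.stenosis.vessel_id == vid:
            st = cfg.stenosis
            arc = np.concatenate([[0.0], np.cumsum(
                np.linalg.norm(np.diff(pts, axis=0), axis=1))])
            prof = 1.0 - (1.0 - st.severity) * np.exp(
                -0.5 * ((arc - st.arc_length_mm) / (st.extent_mm / 2.355)) ** 2)
            radius = radius * prof
        if pts.min() < 2 * s or pts.max() > fov - 2 * s:
            raise ValueError(f"vessel {vid} leaves the field of view")
        _paint_tube(mr, pts, radius, s, cfg.mr_blood)
        _paint_tube(act, pts, radius, s, cfg.act_blood)
        centerlines.append(Centerline(vessel_id=vid, points_mm=pts, radius_mm=radius))

    return Phantom(
        mr_volume=mr,
        activity_volume=act,
        mu_map=mu,
        voxel_size=(s, s, s),
        centerlines=centerlines,
        lv_geometry=lv,
        defect_spec=cfg.defect,
        config=cfg,
        myocardium_mask=myo,
    )


def _aha_angle(dx, dy):
    """Circumferential angle: 0 at the anterior wall (-y), counterclockwise
    as seen from the apex (anterior -> septal -> inferior -> lateral)."""
    return np.arctan2(-dx, -dy) % (2 * np.pi)


def _paint_tube(vol: np.ndarray, pts_mm: np.ndarray, radius_mm: np.ndarray,
                voxel: float, value: float) -> None:
    """Set voxels within the tube's lumen to ``value`` (hard edge)."""
    from scipy.spatial import cKDTree

    # densify centerline so point spacing << voxel
    seg = np.linalg.norm(np.diff(pts_mm, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    fine = np.arange(0.0, arc[-1], voxel / 4.0)
    dense = np.stack([np.interp(fine, arc, pts_mm[:, i]) for i in range(3)], axis=1)
    dense_r = np.interp(fine, arc, radius_mm)

    lo = np.maximum(((dense.min(axis=0) - radius_mm.max()) / voxel - 1).astype(int), 0)
    hi = np.minimum(((dense.max(axis=0) + radius_mm.max()) / voxel + 2).astype(int),
                    vol.shape)
    sub = np.stack(np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)],
                               indexing="ij"), axis=-1).reshape(-1, 3)
    sub_mm = (sub + 0.5) * voxel
    tree = cKDTree(dense)
    dist, idx = tree.query(sub_mm)
    inside = dist <= dense_r[idx]
    sel = sub[inside]
    vol[sel[:, 0], sel[:, 1], sel[:, 2]] = value


# --------------------------------------------------------------------------
# motion model and warping
# --------------------------------------------------------------------------

@dataclass
class MotionModel:
    """Maps a heartbeat index to the heart's respiratory displacement.

    The base component is the rigid translation ``(RL, 0, FH)`` from the
    breathing trace.  With ``nonrigid=True`` the translation is modulated by
    a smooth superior–inferior amplitude gradient (structures near the
    diaphragm move more than the chest apex), giving a ground-truth
    non-rigid deformation proportional to FH amplitude.
    """

    trace: BreathingTrace
    nonrigid: bool = False
    nonrigid_gradient: float = 0.6    # fractional amplitude drop base->apex
    interpolation_order: int = 1

    def displacement(self, beat: int) -> tuple[float, float]:
        """(FH, RL) object displacement in mm at ``beat``."""
        if not 0 <= beat < self.trace.n_beats:
            raise IndexError("beat outside the breathing trace")
        return float(self.trace.fh_mm[beat]), float(self.trace.rl_mm[beat])

    def displacement_field(self, fh: float, rl: float,
                           shape: tuple[int, int, int],
                           voxel: float) -> np.ndarray:
        """Object displacement field (push convention), shape (3, nx, ny, nz), mm."""
        fld = np.zeros((3,) + tuple(shape))
        if self.nonrigid and (fh != 0.0 or rl != 0.0):
            nz = shape[2]
            zc = (np.arange(nz) + 0.5) / nz
            w = 1.0 - self.nonrigid_gradient * zc   # inferior moves most
            fld[0] = rl * w[None, None, :]
            fld[2] = fh * w[None, None, :]
        else:
            fld[0] = rl
            fld[2] = fh
        return fld


def warp_volume(vol: np.ndarray, displacement_mm: np.ndarray, voxel: float,
                order: int = 1, spectral: bool = False) -> np.ndarray:
    """Warp ``vol`` by an object *displacement* field (push convention).

    The output at voxel v samples the input at ``v - d(v)/voxel`` — for a
    pure translation this moves the object by +d.  Linear interpolation by
    default; out-of-volume samples are zero.  Spatially constant fields take
    a fast pure-translation path; with ``spectral=True`` they are applied as
    an exact Fourier-domain phase shift (circular wrap at the edges — the
    physically faithful model of a continuously shifted object sampled on a
    k-space grid).
    """
    d = np.asarray(displacement_mm, dtype=float)
    if d.ndim == 1 or all(np.ptp(d[c]) == 0 for c in range(3)):
        t = d if d.ndim == 1 else np.array([d[c].flat[0] for c in range(3)])
        if spectral:
            return _spectral_shift(vol, t / voxel)
        return ndimage.shift(vol, t / voxel, order=order, mode="constant",
                             cval=0.0)
    coords = np.mgrid[[slice(n) for n in vol.shape]].astype(float)
    coords -= d / voxel
    return ndimage.map_coordinates(vol, coords, order=order, mode="constant", cval=0.0)


def _spectral_shift(vol: np.ndarray, shift_vox: np.ndarray) -> np.ndarray:
    # returns complex: a fractionally shifted real image has no Hermitian
    # spectrum at the Nyquist bin, and the MR signal is complex anyway
    k = np.fft.fftn(vol)
    for ax, s in enumerate(shift_vox):
        if s == 0.0:
            continue
        f = np.fft.fftfreq(vol.shape[ax])
        phase = np.exp(-2j * np.pi * f * s)
        sh = [1, 1, 1]
        sh[ax] = -1
        k = k * phase.reshape(sh)
    return np.fft.ifftn(k)


@dataclass
class DeformedPhantom:
    mr: np.ndarray
    activity: np.ndarray
    mu: np.ndarray
    displacement_mm: np.ndarray      # (3, nx, ny, nz) push field actually used
    clipped: bool = False


def deform_phantom(phantom: Phantom, model: MotionModel, beat: int) -> DeformedPhantom:
    """Warp all three phantom volumes to the respiratory state of ``beat``.

    Returns the exact displacement field used (object displacement, mm) so
    oracle tests can compare estimated motion against the truth.  A zero
    displacement short-circuits to the identity (inputs returned unchanged).
    """
    fh, rl = model.displacement(beat)
    return deform_phantom_to(phantom, model, fh, rl)


def deform_phantom_to(phantom: Phantom, model: MotionModel,
                      fh: float, rl: float,
                      components: tuple[str, ...] = ("mr", "activity", "mu"),
                      spectral: bool = False) -> DeformedPhantom:
    """Warp the phantom to an explicit (FH, RL) displacement in mm.

    ``components`` restricts which volumes are warped (the others are
    returned untouched) — the MR acquisition only needs ``mr``.
    ``spectral`` applies exact Fourier-domain translation (MR signal path);
    it is ignored for non-rigid motion models.
    """
    s = phantom.voxel_size[0]
    shape = phantom.shape
    if fh == 0.0 and rl == 0.0:
        fld = np.zeros((3,) + tuple(shape))
        return DeformedPhantom(phantom.mr_volume, phantom.activity_volume,
                               phantom.mu_map, fld)
    fld = model.displacement_field(fh, rl, shape, s)
    order = model.interpolation_order
    clipped = _heart_clipped(phantom, fh, rl)

    def _w(vol, name):
        if name not in components:
            return vol
        return warp_volume(vol, fld, s, order, spectral=spectral)

    out = DeformedPhantom(
        mr=_w(phantom.mr_volume, "mr"),
        activity=_w(phantom.activity_volume, "activity"),
        mu=_w(phantom.mu_map, "mu"),
        displacement_mm=fld,
        clipped=clipped,
    )
    if clipped:
        import warnings

        warnings.warn("displacement pushes the heart to the volume edge; "
                      "clipped content", stacklevel=2)
    return out


def _heart_clipped(phantom: Phantom, fh: float, rl: float) -> bool:
    lv = phantom.lv_geometry
    fov = phantom.shape[2] * phantom.voxel_size[2]
    zmax = lv.base_z + fh + lv.r_outer
    zmin = lv.apex_z + fh - lv.r_outer
    xmax = lv.center_xy[0] + rl + 1.5 * lv.r_outer
    xmin = lv.center_xy[0] + rl - 1.5 * lv.r_outer
    return zmax > fov or zmin < 0 or xmax > fov or xmin < 0
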