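"""ECG-triggered golden-step Cartesian CMRA acquisition with 2D iNAVs.

One spiral-ordered interleaf of phase encodes is acquired per heartbeat at
that beat's respiratory position, preceded by a low-resolution coronal
image navigator (iNAV).  The phase-encode plane is (RL, FH) = array axes
(x, z); the readout direction (AP, axis y) is fully sampled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .linops import fftc, ifftc
from .phantom import BreathingTrace, MotionModel, Phantom, deform_phantom_to

GOLDEN_ANGLE = 2.0 * np.pi * (1.0 - 2.0 / (1.0 + np.sqrt(5.0)))  # ~2.39996 rad


# --------------------------------------------------------------------------
# trajectory
# --------------------------------------------------------------------------

@dataclass
class CartesianTrajectory:
    """Spiral-ordered interleaves of Cartesian phase-encode points.

    ``interleaves[i]`` is an (L_i, 2) integer array of (pe_rl, pe_fh) grid
    indices, ordered centre-out; the union over interleaves covers the grid
    exactly once.
    """

    matrix_yz: tuple[int, int]
    lines_per_interleaf: int
    interleaves: list[np.ndarray]

    @property
    def n_interleaves(self) -> int:
        return len(self.interleaves)

    def start_angles(self) -> np.ndarray:
        """Angle of the first (innermost) point of each interleaf."""
        n1, n2 = self.matrix_yz
        ang = []
        for arm in self.interleaves:
            f1 = arm[0, 0] - n1 // 2
            f2 = arm[0, 1] - n2 // 2
            ang.append(np.arctan2(f2, f1))
        return np.array(ang)

    def coverage_counts(self) -> np.ndarray:
        cnt = np.zeros(self.matrix_yz, dtype=int)
        for arm in self.interleaves:
            np.add.at(cnt, (arm[:, 0], arm[:, 1]), 1)
        return cnt


def make_trajectory(matrix_yz: tuple[int, int], lines_per_interleaf: int,
                    twist: float = 0.0) -> CartesianTrajectory:
    """Sort the full Cartesian phase-encode grid into golden-angle spiral arms.

    All (pe_rl, pe_fh) points are grouped by their (optionally twisted)
    angular coordinate into equal-count arms; arm i acquired at heartbeat i
    is the unused arm closest to i x golden angle, and each arm is ordered
    centre-out so every beat samples low spatial frequencies first.
    """
    n1, n2 = matrix_yz
    total = n1 * n2
    L = int(lines_per_interleaf)
    if L < 1:
        raise ValueError("lines_per_interleaf must be >= 1")
    if L > total:
        raise ValueError("lines_per_interleaf exceeds the number of grid points")

    u, v = np.meshgrid(np.arange(n1), np.arange(n2), indexing="ij")
    f1 = (u - n1 // 2).ravel()
    f2 = (v - n2 // 2).ravel()
    r = np.hypot(f1, f2)
    a = np.arctan2(f2, f1)
    c = (a - twist * r) % (2.0 * np.pi)

    order = np.lexsort((r, c))
    n_arms = int(np.ceil(total / L))
    chunks = [order[i * L:(i + 1) * L] for i in range(n_arms)]
    centers = np.array([
        # chunks are contiguous in sorted c, so the arithmetic midpoint is safe
        0.5 * (c[ch[0]] + c[ch[-1]]) for ch in chunks
    ])

    # time-order arms so successive start angles advance by the golden angle
    used = np.zeros(n_arms, dtype=bool)
    interleaves = []
    for i in range(n_arms):
        target = (i * GOLDEN_ANGLE) % (2.0 * np.pi)
        d = np.abs((centers - target + np.pi) % (2.0 * np.pi) - np.pi)
        d[used] = np.inf
        j = int(np.argmin(d))
        used[j] = True
        ch = chunks[j]
        ch = ch[np.lexsort((c[ch], r[ch]))]          # centre-out
        pts = np.stack([u.ravel()[ch], v.ravel()[ch]], axis=1)
        interleaves.append(pts)
    return CartesianTrajectory(matrix_yz=(n1, n2), lines_per_interleaf=L,
                               interleaves=interleaves)


# --------------------------------------------------------------------------
# coils
# --------------------------------------------------------------------------

@dataclass
class CoilSet:
    sens: np.ndarray       # (n_coils, nx, ny, nz) complex

    @property
    def n_coils(self) -> int:
        return self.sens.shape[0]

    def rss(self) -> np.ndarray:
        return np.sqrt(np.sum(np.abs(self.sens) ** 2, axis=0))


def simulate_coils(matrix: tuple[int, int, int], n_coils: int = 8) -> CoilSet:
    """Smooth synthetic complex sensitivities: Gaussian lobes placed around
    the torso in the axial plane with gentle linear phase ramps.  A single
    coil yields the constant map 1 (plain Fourier imaging)."""
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    nx, ny, nz = matrix
    if n_coils == 1:
        return CoilSet(np.ones((1, nx, ny, nz), dtype=complex))
    x, y, z = np.meshgrid(np.arange(nx), np.arange(ny), np.arange(nz),
                          indexing="ij")
    cx, cy, cz = (nx - 1) / 2.0, (ny - 1) / 2.0, (nz - 1) / 2.0
    rad = 0.45 * max(nx, ny)
    sigma = 0.20 * max(nx, ny)
    sigma_z = 0.25 * nz
    maps = []
    for k in range(n_coils):
        # two rings staggered along z (anterior/posterior array halves)
        ang = 2.0 * np.pi * (k // 2) / max(n_coils // 2, 1) + (k % 2) * np.pi / 4
        pz = cz + (0.3 if k % 2 else -0.3) * nz
        px = cx + rad * np.cos(ang)
        py = cy + rad * np.sin(ang)
        mag = np.exp(-((x - px) ** 2 + (y - py) ** 2) / (2 * sigma ** 2)
                     - (z - pz) ** 2 / (2 * sigma_z ** 2))
        ph = 2.0 * np.pi * (0.2 * np.cos(ang) * x + 0.2 * np.sin(ang) * y
                            + 0.1 * (k % 2) * z) / nx
        maps.append((0.05 + mag) * np.exp(1j * ph))
    sens = np.stack(maps)
    # normalise so the root-sum-of-squares is order 1 over the object
    rss = np.sqrt(np.sum(np.abs(sens) ** 2, axis=0))
    sens = sens / rss.mean()
    return CoilSet(sens)


# --------------------------------------------------------------------------
# k-space and iNAV containers
# --------------------------------------------------------------------------

@dataclass
class KSpaceData:
    """Per-heartbeat Cartesian interleaf samples.

    ``data[coil, interleaf, line, readout]``; ``line_mask`` marks real lines
    (the last interleaf may be short).  ``accepted`` starts all-True and is
    cleared by outlier rejection downstream.
    """

    data: np.ndarray
    traj: CartesianTrajectory
    beat_index: np.ndarray
    line_mask: np.ndarray
    matrix: tuple[int, int, int]
    voxel_mm: float
    noise_sd: float
    seed: int
    accepted: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.accepted is None:
            self.accepted = np.ones(self.traj.n_interleaves, dtype=bool)

    @property
    def n_coils(self) -> int:
        return self.data.shape[0]

    def grid_weights(self, weight_per_interleaf: np.ndarray) -> np.ndarray:
        """Spread per-interleaf weights onto the (pe_rl, pe_fh) grid."""
        n1, n2 = self.traj.matrix_yz
        w = np.zeros((n1, n2))
        for i, arm in enumerate(self.traj.interleaves):
            w[arm[:, 0], arm[:, 1]] = weight_per_interleaf[i]
        return w

    def assemble(self, weight_per_interleaf: np.ndarray | None = None,
                 phase_per_interleaf: np.ndarray | None = None) -> np.ndarray:
        """Grid all lines to full k-space, shape (n_coils, nx, ny, nz).

        Optional per-interleaf scalar weights and per-line complex phases
        (as produced by the translational correction) are applied while
        gridding.  Unsampled/zero-weight points stay zero.
        """
        nx, ny, nz = self.matrix
        out = np.zeros((self.n_coils, nx, ny, nz), dtype=complex)
        for i, arm in enumerate(self.traj.interleaves):
            w = 1.0 if weight_per_interleaf is None else weight_per_interleaf[i]
            if w == 0.0:
                continue
            li = len(arm)                          # last interleaf may be short
            lines = self.data[:, i, :li, :]        # (coils, L_i, ny)
            if phase_per_interleaf is not None:
                lines = lines * phase_per_interleaf[i][None, :li, None]
            # advanced indexing on axes 1 and 3 puts the line axis first;
            # interleaves are disjoint so plain assignment is safe
            out[:, arm[:, 0], :, arm[:, 1]] = w * lines.transpose(1, 0, 2)
        return out


@dataclass
class INavSeries:
    """Per-beat coronal 2D navigator images on the display grid.

    Acquired with ``n_lines`` central RL phase encodes (coarse RL
    resolution), full resolution along FH, then interpolated to
    ``display_pixel_mm`` for motion estimation.
    """

    images: np.ndarray              # (n_beats, X, Z) float, display grid
    display_pixel_mm: float
    n_lines: int
    voxel_mm: float
    matrix: tuple[int, int, int]

    @property
    def n_beats(self) -> int:
        return self.images.shape[0]


def _make_inav(mr_volume: np.ndarray, n_lines: int, voxel_mm: float,
               display_pixel_mm: float) -> np.ndarray:
    proj = np.asarray(mr_volume, dtype=complex).sum(axis=1)  # coronal (RL, FH)
    k = fftc(proj, axes=(0,))
    nx = proj.shape[0]
    keep = np.zeros(nx, dtype=bool)
    c0 = nx // 2 - n_lines // 2
    keep[c0:c0 + n_lines] = True
    k[~keep, :] = 0.0
    low = np.abs(ifftc(k, axes=(0,)))
    zoomf = voxel_mm / display_pixel_mm
    return ndimage.zoom(low, zoomf, order=3, mode="nearest")


def simulate_inavs(phantom: Phantom, model: MotionModel, trace: BreathingTrace,
                   n_beats: int | None = None, n_lines: int = 14,
                   display_pixel_mm: float = 1.0) -> INavSeries:
    """Generate the per-beat iNAV series alone (no CMRA k-space)."""
    n = trace.n_beats if n_beats is None else n_beats
    imgs = []
    cache: dict[tuple[float, float], np.ndarray] = {}
    for b in range(n):
        fh, rl = model.displacement(b)
        key = (round(fh, 9), round(rl, 9))
        if key not in cache:
            dp = deform_phantom_to(phantom, model, fh, rl, components=("mr",),
                                   spectral=not model.nonrigid)
            cache[key] = _make_inav(dp.mr, n_lines, phantom.voxel_size[0],
                                    display_pixel_mm)
            if len(cache) > 512:
                cache.clear()
        imgs.append(cache[key])
    return INavSeries(images=np.stack(imgs), display_pixel_mm=display_pixel_mm,
                      n_lines=n_lines, voxel_mm=phantom.voxel_size[0],
                      matrix=phantom.shape)


def acquire_cmra(phantom: Phantom, model: MotionModel, trace: BreathingTrace,
                 traj: CartesianTrajectory, coils: CoilSet,
                 noise_sd: float = 0.0, seed: int = 0,
                 inav_lines: int = 14) -> tuple[KSpaceData, INavSeries]:
    """Simulate the segmented CMRA acquisition.

    For every heartbeat the phantom is warped to that beat's respiratory
    state, an iNAV is formed from the coronal projection, and the beat's
    interleaf of the 3D coil-weighted Fourier transform is sampled along
    the fully-resolved readout, with circular complex Gaussian noise of
    standard deviation ``noise_sd`` added per sample.
    """
    nx, ny, nz = phantom.shape
    if traj.matrix_yz != (nx, nz):
        raise ValueError("trajectory phase-encode grid does not match phantom")
    n_int = traj.n_interleaves
    if n_int > trace.n_beats:
        raise ValueError("trajectory needs more heartbeats than the trace has")

    rng = np.random.default_rng(seed)
    L = traj.lines_per_interleaf
    data = np.zeros((coils.n_coils, n_int, L, ny), dtype=complex)
    line_mask = np.zeros((n_int, L), dtype=bool)
    inavs = []
    s = phantom.voxel_size[0]

    kcache: dict[tuple[float, float], np.ndarray] = {}
    icache: dict[tuple[float, float], np.ndarray] = {}
    for i in range(n_int):
        fh, rl = model.displacement(i)
        key = (round(fh, 9), round(rl, 9))
        if key not in kcache:
            dp = deform_phantom_to(phantom, model, fh, rl, components=("mr",),
                                   spectral=not model.nonrigid)
            kfull = fftc(coils.sens * np.asarray(dp.mr, dtype=complex),
                         axes=(1, 2, 3))
            kcache[key] = kfull
            icache[key] = _make_inav(dp.mr, inav_lines, s, 1.0)
            if len(kcache) > 8:   # bound memory for continuously varying motion
                oldest = next(iter(kcache))
                if oldest != key:
                    kcache.pop(oldest)
                    icache.pop(oldest, None)
        kfull = kcache[key]
        inavs.append(icache[key])
        arm = traj.interleaves[i]
        li = len(arm)
        data[:, i, :li, :] = kfull[:, arm[:, 0], :, arm[:, 1]].transpose(1, 0, 2)
        line_mask[i, :li] = True

    if noise_sd > 0:
        noise = rng.standard_normal(data.shape) + 1j * rng.standard_normal(data.shape)
        data = data + noise_sd / np.sqrt(2.0) * noise * line_mask[None, :, :, None]

    ksp = KSpaceData(data=data, traj=traj, beat_index=np.arange(n_int),
                     line_mask=line_mask, matrix=phantom.shape, voxel_mm=s,
                     noise_sd=noise_sd, seed=seed)
    nav = INavSeries(images=np.stack(inavs), display_pixel_mm=1.0,
                     n_lines=inav_lines, voxel_mm=s, matrix=phantom.shape)
    return ksp, nav
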