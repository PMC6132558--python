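"""Linear operators used by the reconstruction modules.

Every operator exposes ``forward`` and ``adjoint`` that are exact matrix
transposes of each other (verified by dot-product tests), which is what the
conjugate-gradient solvers require.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


# ---- centred orthonormal FFTs --------------------------------------------

def fftc(x: np.ndarray, axes=None) -> np.ndarray:
    """Centred orthonormal FFT: DC and image centre both at N//2."""
    axes = tuple(range(x.ndim)) if axes is None else axes
    return np.fft.fftshift(
        np.fft.fftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def ifftc(x: np.ndarray, axes=None) -> np.ndarray:
    axes = tuple(range(x.ndim)) if axes is None else axes
    return np.fft.fftshift(
        np.fft.ifftn(np.fft.ifftshift(x, axes=axes), axes=axes, norm="ortho"),
        axes=axes,
    )


def freq_index(n: int) -> np.ndarray:
    """Centred integer frequencies (cycles per field of view) for fftc."""
    return np.arange(n) - n // 2


# ---- trilinear warp with exact transpose ---------------------------------

@dataclass
class WarpOp:
    """Pull-warp by a sampling-offset field: out(v) = in(v + f(v)).

    ``field_vox`` has shape (3, nx, ny, nz) in voxel units.  ``forward`` is
    trilinear gather; ``adjoint`` is the scatter with identical weights (the
    matrix transpose, not the inverse warp).  Samples outside the volume are
    dropped on both sides.
    """

    field_vox: np.ndarray

    def __post_init__(self) -> None:
        shape = self.field_vox.shape[1:]
        self.shape = shape
        coords = np.mgrid[[slice(n) for n in shape]].astype(np.float64)
        coords = coords + self.field_vox
        base = np.floor(coords).astype(np.int64)
        frac = coords - base
        n_vox = int(np.prod(shape))
        strides = np.array(
            [shape[1] * shape[2], shape[2], 1], dtype=np.int64
        ).reshape(3, 1)

        idx_list = []
        w_list = []
        for corner in range(8):
            off = np.array([(corner >> 2) & 1, (corner >> 1) & 1, corner & 1])
            ci = base + off.reshape(3, 1, 1, 1)
            w = np.ones(shape)
            valid = np.ones(shape, dtype=bool)
            for a in range(3):
                fa = frac[a]
                w = w * np.where(off[a] == 1, fa, 1.0 - fa)
                valid &= (ci[a] >= 0) & (ci[a] < shape[a])
            ci = np.clip(ci, 0, np.array(shape).reshape(3, 1, 1, 1) - 1)
            flat = (ci.reshape(3, -1) * strides).sum(axis=0)
            w = (w * valid).ravel()
            idx_list.append(flat)
            w_list.append(w)
        self._idx = np.stack(idx_list)      # (8, n_vox)
        self._w = np.stack(w_list)          # (8, n_vox)
        self._n_vox = n_vox

    def forward(self, vol: np.ndarray) -> np.ndarray:
        flat = vol.ravel()
        out = np.zeros(self._n_vox, dtype=vol.dtype)
        for k in range(8):
            out += self._w[k] * flat[self._idx[k]]
        return out.reshape(self.shape)

    def adjoint(self, vol: np.ndarray) -> np.ndarray:
        flat = vol.ravel()
        out = np.zeros(self._n_vox, dtype=vol.dtype)
        for k in range(8):
            np.add.at(out, self._idx[k], self._w[k] * flat)
        return out.reshape(self.shape)


def identity_warp(shape) -> WarpOp:
    return WarpOp(np.zeros((3,) + tuple(shape)))


@dataclass
class SpectralShiftOp:
    """Exact circular translation by a constant offset (voxels).

    Implements the pull warp out(v) = in(v + t) as a unitary k-space phase
    ramp; the adjoint is the inverse shift, so the pair is exactly adjoint
    and, unlike trilinear interpolation, attenuation-free.
    """

    shift_vox: np.ndarray       # (3,), sampling offset t (pull convention)

    def _apply(self, vol: np.ndarray, sign: float) -> np.ndarray:
        k = np.fft.fftn(vol)
        for ax, t in enumerate(self.shift_vox):
            if t == 0.0:
                continue
            f = np.fft.fftfreq(vol.shape[ax])
            sh = [1] * vol.ndim
            sh[ax] = -1
            k = k * np.exp(sign * 2j * np.pi * f * t).reshape(sh)
        out = np.fft.ifftn(k)
        return out if np.iscomplexobj(vol) else out.real

    def forward(self, vol: np.ndarray) -> np.ndarray:
        # out(v) = in(v + t) is a shift of the content by -t
        return self._apply(vol, +1.0)

    def adjoint(self, vol: np.ndarray) -> np.ndarray:
        return self._apply(vol, -1.0)


def make_warp(field_vox: np.ndarray):
    """Warp operator for a pull field: exact spectral shift when the field
    is spatially constant, trilinear gather/scatter otherwise."""
    if all(np.ptp(field_vox[c]) == 0 for c in range(3)):
        t = np.array([field_vox[c].flat[0] for c in range(3)])
        return SpectralShiftOp(t)
    return WarpOp(field_vox)


@dataclass
class CoilOp:
    """Multiplication by complex coil sensitivities.

    forward: image -> (n_coils, ...) coil images; adjoint: conjugate
    sensitivity combination.
    """

    sens: np.ndarray     # (n_coils, nx, ny, nz) complex

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.sens * x[None]

    def adjoint(self, y: np.ndarray) -> np.ndarray:
        return np.sum(np.conj(self.sens) * y, axis=0)


@dataclass
class GridSampleOp:
    """Cartesian k-space sampling: keep grid points where mask is nonzero.

    Operates on fully gridded k-space (any leading coil axis); forward
    multiplies by the mask (optionally weighted), adjoint is the same
    multiplication (diagonal operator, real weights).
    """

    mask: np.ndarray     # broadcastable to the k-space grid, real >= 0

    def forward(self, k: np.ndarray) -> np.ndarray:
        return k * self.mask

    def adjoint(self, k: np.ndarray) -> np.ndarray:
        return k * self.mask


# ---- conjugate gradient on the normal equations --------------------------

def cg_solve(normal_op, rhs: np.ndarray, n_iter: int = 15, tol: float = 1e-6,
             precond=None):
    """(Preconditioned) conjugate gradient for A x = b, A Hermitian PSD.

    ``precond`` is an optional function applying M^-1 (e.g. division by the
    coil root-sum-of-squares).  Returns (x, residual_log) with the relative
    residual norm after each iteration.
    """
    x = np.zeros_like(rhs)
    r = rhs.copy()
    z = precond(r) if precond else r
    p = z.copy()
    rz = np.vdot(r, z).real
    b_norm = np.sqrt(np.vdot(rhs, rhs).real)
    if b_norm == 0:
        return x, [0.0]
    log = []
    for _ in range(n_iter):
        ap = normal_op(p)
        denom = np.vdot(p, ap).real
        if denom <= 0:
            break
        alpha = rz / denom
        x = x + alpha * p
        r = r - alpha * ap
        rel = np.sqrt(np.vdot(r, r).real) / b_norm
        log.append(rel)
        if rel < tol:
            break
        z = precond(r) if precond else r
        rz_new = np.vdot(r, z).real
        p = z + (rz_new / rz) * p
        rz = rz_new
    return x, log
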