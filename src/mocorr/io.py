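"""File formats: NIfTI volumes, HDF5 raw-data containers, CSV tables."""

from __future__ import annotations

import csv
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np

from .acquisition import CartesianTrajectory, INavSeries, KSpaceData
from .motion import BinAssignment, MotionTable
from .phantom import BreathingTrace, Centerline


def save_nifti(path, volume: np.ndarray, voxel_mm: float,
               descrip: str = "") -> None:
    vol = np.abs(volume) if np.iscomplexobj(volume) else np.asarray(volume)
    img = nib.Nifti1Image(vol.astype(np.float32), np.diag([voxel_mm] * 3 + [1.0]))
    if descrip:
        img.header["descrip"] = descrip.encode()[:79]
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, float]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), float(img.header.get_zooms()[0])


def save_field_nifti(path, field_mm: np.ndarray, voxel_mm: float) -> None:
    """Deformation field (3, nx, ny, nz) as a 4D NIfTI, components last."""
    arr = np.moveaxis(field_mm, 0, -1).astype(np.float32)
    img = nib.Nifti1Image(arr, np.diag([voxel_mm] * 3 + [1.0]))
    nib.save(img, str(path))


def save_trace_csv(path, trace: BreathingTrace) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["beat", "time_s", "fh_mm", "rl_mm", "deep_flag"])
        for i in range(trace.n_beats):
            w.writerow([i, f"{trace.heartbeat_times[i]:.4f}",
                        f"{trace.fh_mm[i]:.4f}", f"{trace.rl_mm[i]:.4f}",
                        int(trace.deep_breath_flag[i])])


def load_trace_csv(path, seed: int = 0) -> BreathingTrace:
    rows = np.genfromtxt(path, delimiter=",", skip_header=1)
    rows = np.atleast_2d(rows)
    return BreathingTrace(heartbeat_times=rows[:, 1], fh_mm=rows[:, 2],
                          rl_mm=rows[:, 3],
                          deep_breath_flag=rows[:, 4].astype(bool), seed=seed)


def save_centerlines_csv(path, centerlines: list[Centerline]) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(["vessel_id", "point_index", "x_mm", "y_mm", "z_mm",
                    "radius_mm"])
        for cl in centerlines:
            for i, (p, r) in enumerate(zip(cl.points_mm, cl.radius_mm)):
                w.writerow([cl.vessel_id, i, f"{p[0]:.3f}", f"{p[1]:.3f}",
                            f"{p[2]:.3f}", f"{r:.3f}"])


def save_motion_csv(path, motion: MotionTable, bins: BinAssignment | None = None
                    ) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        head = ["beat", "fh_mm", "rl_mm", "score"]
        if bins is not None:
            head.append("bin")
        w.writerow(head)
        for i in range(motion.n_beats):
            row = [i, f"{motion.fh_mm[i]:.4f}", f"{motion.rl_mm[i]:.4f}",
                   f"{motion.score[i]:.4f}"]
            if bins is not None:
                row.append(int(bins.labels[i]))
            w.writerow(row)


def save_acquisition(path, kspace: KSpaceData, inavs: INavSeries,
                     coils=None) -> None:
    """Write k-space + iNAV series (and optionally the coil maps) to one
    structured HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=kspace.data.astype(np.complex64))
        if coils is not None:
            f.create_dataset("coils", data=coils.sens.astype(np.complex64))
        traj = np.stack([np.pad(arm, ((0, kspace.traj.lines_per_interleaf
                                       - len(arm)), (0, 0)), constant_values=-1)
                         for arm in kspace.traj.interleaves])
        f.create_dataset("traj", data=traj.astype(np.int16))
        f.create_dataset("beat_index", data=kspace.beat_index)
        f.create_dataset("line_mask", data=kspace.line_mask)
        f.create_dataset("inavs", data=inavs.images.astype(np.float32))
        f.attrs["matrix"] = kspace.matrix
        f.attrs["voxel_size_mm"] = kspace.voxel_mm
        f.attrs["noise_sd"] = kspace.noise_sd
        f.attrs["seed"] = kspace.seed
        f.attrs["inav_lines"] = inavs.n_lines
        f.attrs["inav_pixel_mm"] = inavs.display_pixel_mm
        f.attrs["lines_per_interleaf"] = kspace.traj.lines_per_interleaf


def load_acquisition(path) -> tuple[KSpaceData, INavSeries]:
    with h5py.File(path, "r") as f:
        traj_arr = f["traj"][()]
        interleaves = [arm[arm[:, 0] >= 0].astype(int) for arm in traj_arr]
        matrix = tuple(int(m) for m in f.attrs["matrix"])
        traj = CartesianTrajectory(
            matrix_yz=(matrix[0], matrix[2]),
            lines_per_interleaf=int(f.attrs["lines_per_interleaf"]),
            interleaves=interleaves)
        ksp = KSpaceData(
            data=f["kspace"][()].astype(complex), traj=traj,
            beat_index=f["beat_index"][()], line_mask=f["line_mask"][()],
            matrix=matrix, voxel_mm=float(f.attrs["voxel_size_mm"]),
            noise_sd=float(f.attrs["noise_sd"]), seed=int(f.attrs["seed"]))
        nav = INavSeries(images=f["inavs"][()].astype(float),
                         display_pixel_mm=float(f.attrs["inav_pixel_mm"]),
                         n_lines=int(f.attrs["inav_lines"]),
                         voxel_mm=ksp.voxel_mm, matrix=matrix)
    return ksp, nav


def save_sinograms(path, sinos) -> None:
    with h5py.File(path, "w") as f:
        for b in range(sinos.n_bins):
            f.create_dataset(f"sino/bin_{b}", data=sinos.counts[b])
            f.create_dataset(f"att/bin_{b}", data=sinos.att[b].astype(np.float32))
        f.create_dataset("time_fraction", data=sinos.time_fraction)
        g = f.create_group("geometry")
        g.attrs["n_angles"] = sinos.geom.n_angles
        g.attrs["n_rad"] = sinos.geom.n_rad
        g.attrs["rad_spacing_mm"] = sinos.geom.rad_spacing_mm
        g.attrs["voxel_mm"] = sinos.geom.voxel_mm
        g.attrs["psf_fwhm_mm"] = sinos.geom.psf_fwhm_mm
        f.attrs["seed"] = sinos.seed
        f.attrs["total_counts"] = sinos.total_counts


def load_sinograms(path):
    from .pet import PETGeometry, SinogramSet

    with h5py.File(path, "r") as f:
        n_bins = len(f["sino"])
        counts = np.stack([f[f"sino/bin_{b}"][()] for b in range(n_bins)])
        att = np.stack([f[f"att/bin_{b}"][()].astype(float)
                        for b in range(n_bins)])
        g = f["geometry"]
        geom = PETGeometry(n_angles=int(g.attrs["n_angles"]),
                           n_rad=int(g.attrs["n_rad"]),
                           rad_spacing_mm=float(g.attrs["rad_spacing_mm"]),
                           voxel_mm=float(g.attrs["voxel_mm"]),
                           psf_fwhm_mm=float(g.attrs["psf_fwhm_mm"]))
        return SinogramSet(counts=counts, att=att,
                           time_fraction=f["time_fraction"][()], geom=geom,
                           seed=int(f.attrs["seed"]),
                           total_counts=float(f.attrs["total_counts"]))


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
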