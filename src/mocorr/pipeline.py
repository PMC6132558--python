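"""End-to-end experiment: simulate -> acquire -> estimate -> reconstruct ->
measure, with and without motion correction.

``run_experiment`` is the canonical comparison the framework exists for:
it produces NMC and MC CMRA and PET volumes from the same simulated
acquisition and summarises the image-quality change (vessel length and
sharpness per vessel, 17-segment PET signal change).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as mio
from .acquisition import acquire_cmra, make_trajectory, simulate_coils
from .metrics import (PolarMap, VesselMetrics, polar_map_17, relative_increase,
                      vessel_length, vessel_sharpness)
from .motion import (BinAssignment, MotionTable, OutlierRule, assign_bins,
                     correct_translational, default_template,
                     estimate_translation, soft_weights)
from .mr_recon import (RegistrationParams, mocomp_cmra, recon_nmc,
                       register_bins, sense_bin)
from .pet import PETGeometry, Projector, pet_mc, pet_nmc, simulate_pet, warp_mumap
from .phantom import (DefectSpec, MotionModel, PhantomConfig, StenosisSpec,
                      build_phantom, simulate_breathing)


@dataclass
class BreathingParams:
    rr_interval_s: float = 1.0
    amplitude_mm: float = 10.0
    period_s: float = 4.0
    drift_mm_per_min: float = 0.0
    deep_breath_prob: float = 0.05
    deep_breath_scale: float = 2.0
    rl_fraction: float = 0.3


@dataclass
class AcquisitionParams:
    lines_per_interleaf: int = 24
    n_coils: int = 8
    noise_sd: float = 0.01
    inav_lines: int = 14


@dataclass
class MotionParams:
    n_bins: int = 4
    outlier_method: str = "iqr"
    outlier_k: float = 1.5
    soft_width_mm: float | None = None    # None = half bin spacing


@dataclass
class ReconParams:
    n_iter: int = 15
    tol: float = 1e-6
    reg_levels: tuple[int, ...] = (4, 2, 1)
    reg_iterations: tuple[int, ...] = (80, 60, 40)


@dataclass
class PETParams:
    total_counts: float = 1.0e6
    n_angles: int = 96
    n_iter: int = 3
    n_subsets: int = 21
    psf_fwhm_mm: float = 4.5


@dataclass
class ExperimentConfig:
    matrix: int = 64
    voxel_mm: float = 2.0
    seed: int = 0
    breathing: BreathingParams = field(default_factory=BreathingParams)
    acquisition: AcquisitionParams = field(default_factory=AcquisitionParams)
    motion: MotionParams = field(default_factory=MotionParams)
    recon: ReconParams = field(default_factory=ReconParams)
    pet: PETParams = field(default_factory=PETParams)
    nonrigid_motion: bool = False
    defect: bool = True
    use_true_fields: bool = False     # bypass registration (oracle mode)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as f:
            d = yaml.safe_load(f) or {}
        return cls(
            **{k: v for k, v in d.items()
               if k in ("matrix", "voxel_mm", "seed", "nonrigid_motion",
                        "defect", "use_true_fields")},
            breathing=BreathingParams(**d.get("breathing", {})),
            acquisition=AcquisitionParams(**d.get("acquisition", {})),
            motion=MotionParams(**d.get("motion", {})),
            recon=ReconParams(**d.get("recon", {})),
            pet=PETParams(**d.get("pet", {})),
        )


@dataclass
class ExperimentReport:
    config: ExperimentConfig
    config_hash: str
    phantom: object
    trace: object
    motion_table: MotionTable
    bins: BinAssignment
    cmra_nmc: object
    cmra_mc: object
    pet_nmc: object
    pet_mc: object
    fields: object
    vessel_nmc: list[VesselMetrics]
    vessel_mc: list[VesselMetrics]
    polar_nmc: PolarMap
    polar_mc: PolarMap
    polar_increase: PolarMap
    summary: dict
    timings: dict


def _fan_seed(seed: int, k: int) -> int:
    return int((seed * 1000003 + k) % (2 ** 31 - 1))


def run_experiment(config: ExperimentConfig | None = None,
                   out_dir: str | Path | None = None) -> ExperimentReport:
    """Run the full simulation + reconstruction + analysis experiment."""
    cfg = config or ExperimentConfig()
    timings = {}
    t0 = time.time()

    # ---- phantom + breathing ----
    pcfg = PhantomConfig(matrix=cfg.matrix, voxel_mm=cfg.voxel_mm,
                         defect=DefectSpec() if cfg.defect else None,
                         stenosis=StenosisSpec())
    phantom = build_phantom(pcfg)
    traj = make_trajectory((cfg.matrix, cfg.matrix),
                           cfg.acquisition.lines_per_interleaf)
    b = cfg.breathing
    trace = simulate_breathing(
        n_beats=traj.n_interleaves, rr_interval=b.rr_interval_s,
        amplitude=b.amplitude_mm, period=b.period_s,
        drift=b.drift_mm_per_min, deep_breath_prob=b.deep_breath_prob,
        deep_breath_scale=b.deep_breath_scale, rl_fraction=b.rl_fraction,
        seed=_fan_seed(cfg.seed, 1))
    model = MotionModel(trace=trace, nonrigid=cfg.nonrigid_motion)
    timings["phantom"] = time.time() - t0

    # ---- acquisition ----
    t0 = time.time()
    coils = simulate_coils(phantom.shape, cfg.acquisition.n_coils)
    kspace, inavs = acquire_cmra(phantom, model, trace, traj, coils,
                                 noise_sd=cfg.acquisition.noise_sd,
                                 seed=_fan_seed(cfg.seed, 2),
                                 inav_lines=cfg.acquisition.inav_lines)
    timings["acquire"] = time.time() - t0

    # ---- motion estimation + binning ----
    t0 = time.time()
    template = default_template(inavs, phantom.lv_geometry)
    motion_table = estimate_translation(inavs, template)
    static = np.ptp(motion_table.fh_mm) < 1e-6
    n_bins = 1 if static else cfg.motion.n_bins
    bins = assign_bins(motion_table, n_bins=n_bins,
                       outlier_rule=OutlierRule(method=cfg.motion.outlier_method,
                                                k=cfg.motion.outlier_k))
    bins_soft = soft_weights(motion_table, bins, cfg.motion.soft_width_mm)
    ksp_corr = correct_translational(kspace, motion_table, bins_soft)
    timings["motion"] = time.time() - t0

    # ---- MR reconstruction ----
    t0 = time.time()
    r = cfg.recon
    cmra_nmc = recon_nmc(kspace, coils, n_iter=r.n_iter, tol=r.tol)
    bin_imgs = [sense_bin(ksp_corr, bins_soft, coils, bi,
                          n_iter=r.n_iter, tol=r.tol)
                for bi in range(bins_soft.n_bins)]
    if bins_soft.n_bins > 1:
        if cfg.use_true_fields:
            from .mr_recon import translation_field_set
            fields = translation_field_set(bins_soft, phantom.shape,
                                           cfg.voxel_mm)
        else:
            fields = register_bins(
                bin_imgs, bins_soft.reference_bin,
                RegistrationParams(levels=r.reg_levels,
                                   iterations=r.reg_iterations))
        cmra_mc = mocomp_cmra(ksp_corr, bins_soft, coils, fields,
                              n_iter=r.n_iter, tol=r.tol)
    else:
        from .mr_recon import DeformationFieldSet
        fields = DeformationFieldSet(
            fields_mm=np.zeros((1, 3) + tuple(phantom.shape)),
            reference_bin=0, voxel_mm=cfg.voxel_mm)
        cmra_mc = mocomp_cmra(ksp_corr, bins_soft, coils, fields,
                              n_iter=r.n_iter, tol=r.tol)
    timings["mr_recon"] = time.time() - t0

    # ---- PET ----
    t0 = time.time()
    p = cfg.pet
    geom = PETGeometry(n_angles=p.n_angles, n_rad=cfg.matrix,
                       rad_spacing_mm=cfg.voxel_mm, voxel_mm=cfg.voxel_mm,
                       psf_fwhm_mm=p.psf_fwhm_mm)
    sinos, _mu_truth = simulate_pet(phantom, model, bins, p.total_counts,
                                    geom, seed=_fan_seed(cfg.seed, 3))
    projector = Projector(geom, phantom.shape)
    pet_img_nmc = pet_nmc(sinos, phantom.mu_map, phantom.shape,
                          n_iter=p.n_iter, n_subsets=p.n_subsets,
                          projector=projector)
    mumaps = warp_mumap(phantom.mu_map, fields)
    pet_img_mc = pet_mc(sinos, mumaps, fields, phantom.shape,
                        n_iter=p.n_iter, n_subsets=p.n_subsets,
                        projector=projector)
    timings["pet"] = time.time() - t0

    # ---- metrics ----
    t0 = time.time()
    vm_nmc, vm_mc = [], []
    for cl in phantom.centerlines:
        sn = vessel_sharpness(cmra_nmc, cl, cfg.voxel_mm)
        sm = vessel_sharpness(cmra_mc, cl, cfg.voxel_mm)
        sn = VesselMetrics(cl.vessel_id,
                           vessel_length(cmra_nmc, cl, cfg.voxel_mm),
                           sn.sharpness_pct, sn.per_point_sharpness,
                           sn.per_point_contrast)
        sm = VesselMetrics(cl.vessel_id,
                           vessel_length(cmra_mc, cl, cfg.voxel_mm),
                           sm.sharpness_pct, sm.per_point_sharpness,
                           sm.per_point_contrast)
        vm_nmc.append(sn)
        vm_mc.append(sm)
    polar_nmc = polar_map_17(pet_img_nmc, phantom.lv_geometry,
                             phantom.myocardium_mask, cfg.voxel_mm)
    polar_mc = polar_map_17(pet_img_mc, phantom.lv_geometry,
                            phantom.myocardium_mask, cfg.voxel_mm)
    polar_inc = relative_increase(polar_mc, polar_nmc)
    timings["metrics"] = time.time() - t0

    summary = {"config_hash": cfg.config_hash(), "seed": cfg.seed}
    for vn, vm in zip(vm_nmc, vm_mc):
        vid = vn.vessel_id
        summary[f"{vid}_length_nmc_mm"] = vn.visible_length_mm
        summary[f"{vid}_length_mc_mm"] = vm.visible_length_mm
        summary[f"{vid}_length_change_pct"] = (
            100.0 * (vm.visible_length_mm - vn.visible_length_mm)
            / vn.visible_length_mm if vn.visible_length_mm > 0 else np.nan)
        summary[f"{vid}_sharpness_nmc_pct"] = vn.sharpness_pct
        summary[f"{vid}_sharpness_mc_pct"] = vm.sharpness_pct
        summary[f"{vid}_sharpness_change_pct"] = (
            100.0 * (vm.sharpness_pct - vn.sharpness_pct) / vn.sharpness_pct)
    myo = phantom.myocardium_mask
    summary["pet_myo_mean_nmc"] = float(pet_img_nmc.magnitude[myo].mean())
    summary["pet_myo_mean_mc"] = float(pet_img_mc.magnitude[myo].mean())
    summary["pet_myo_change_pct"] = (
        100.0 * (summary["pet_myo_mean_mc"] - summary["pet_myo_mean_nmc"])
        / summary["pet_myo_mean_nmc"])
    with np.errstate(invalid="ignore"):
        summary["pet_polar_mean_increase_pct"] = float(
            np.nanmean(polar_inc.values))

    report = ExperimentReport(
        config=cfg, config_hash=cfg.config_hash(), phantom=phantom,
        trace=trace, motion_table=motion_table, bins=bins_soft,
        cmra_nmc=cmra_nmc, cmra_mc=cmra_mc, pet_nmc=pet_img_nmc,
        pet_mc=pet_img_mc, fields=fields, vessel_nmc=vm_nmc, vessel_mc=vm_mc,
        polar_nmc=polar_nmc, polar_mc=polar_mc, polar_increase=polar_inc,
        summary=summary, timings=timings)
    if out_dir is not None:
        _write_report(report, out_dir)
    return report


def _write_report(report: ExperimentReport, out_dir) -> None:
    d = mio.ensure_dir(out_dir)
    cfg = report.config
    cfg.to_yaml(d / "config.yaml")
    v = cfg.voxel_mm
    tag = f"mocorr {report.config_hash} seed={cfg.seed}"
    mio.save_nifti(d / "cmra_nmc.nii.gz", report.cmra_nmc.magnitude, v, tag)
    mio.save_nifti(d / "cmra_mc.nii.gz", report.cmra_mc.magnitude, v, tag)
    mio.save_nifti(d / "pet_nmc.nii.gz", report.pet_nmc.magnitude, v, tag)
    mio.save_nifti(d / "pet_mc.nii.gz", report.pet_mc.magnitude, v, tag)
    mio.save_trace_csv(d / "trace.csv", report.trace)
    mio.save_motion_csv(d / "motion.csv", report.motion_table, report.bins)
    mio.save_centerlines_csv(d / "centerlines.csv",
                             report.phantom.centerlines)
    payload = dict(report.summary)
    payload["polar_nmc"] = report.polar_nmc.values.tolist()
    payload["polar_mc"] = report.polar_mc.values.tolist()
    payload["polar_increase_pct"] = report.polar_increase.values.tolist()
    payload["timings_s"] = {k: round(t, 2) for k, t in report.timings.items()}
    with open(d / "summary.json", "w") as f:
        json.dump(payload, f, indent=2, default=float)


def make_fixtures(size: str = "tiny", seed: int = 0) -> dict:
    """Generate the shared test scenes.

    ``tiny``: 32-voxel matrix, 2 coils, quick; ``small``: 64-voxel matrix
    with the default acquisition settings.  Returns a dict of the simulated
    objects keyed by name; the static variant (zero breathing amplitude) is
    included for zero-motion equivalence tests.
    """
    if size == "tiny":
        matrix, coils, lines = 32, 2, 64
    elif size == "small":
        matrix, coils, lines = 64, 8, 24
    else:
        raise ValueError("size must be 'tiny' or 'small'")
    cfg = ExperimentConfig(matrix=matrix, seed=seed)
    cfg.acquisition.n_coils = coils
    cfg.acquisition.lines_per_interleaf = lines
    phantom = build_phantom(PhantomConfig(matrix=matrix,
                                          defect=DefectSpec(),
                                          stenosis=StenosisSpec()))
    traj = make_trajectory((matrix, matrix), lines)
    trace = simulate_breathing(n_beats=traj.n_interleaves,
                               amplitude=cfg.breathing.amplitude_mm,
                               deep_breath_prob=0.0,
                               seed=_fan_seed(seed, 1))
    static_trace = simulate_breathing(n_beats=traj.n_interleaves, amplitude=0.0,
                                      deep_breath_prob=0.0,
                                      seed=_fan_seed(seed, 1))
    return {"config": cfg, "phantom": phantom, "traj": traj, "trace": trace,
            "static_trace": static_trace,
            "coils": simulate_coils(phantom.shape, coils)}
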