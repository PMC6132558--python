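"""Motion-corrected vs uncorrected CMRA reconstruction.

Acquires a breathing CMRA dataset, corrects each beat to its bin centre by
a k-space phase shift, reconstructs per-bin images by iterative SENSE,
estimates bin-to-bin deformation fields and solves the joint
motion-compensated reconstruction; prints the vessel sharpness both ways.
"""

import numpy as np

import mocorr as mc

phantom = mc.build_phantom(mc.PhantomConfig(
    matrix=64, defect=mc.DefectSpec(), stenosis=mc.StenosisSpec()))
traj = mc.make_trajectory((64, 64), lines_per_interleaf=24)
trace = mc.simulate_breathing(traj.n_interleaves, amplitude=10.0,
                              deep_breath_prob=0.0, seed=4)
model = mc.MotionModel(trace)
coils = mc.simulate_coils(phantom.shape, 8)
kspace, inavs = mc.acquire_cmra(phantom, model, trace, traj, coils,
                                noise_sd=0.01, seed=4)

table = mc.estimate_translation(
    inavs, mc.default_template(inavs, phantom.lv_geometry))
bins = mc.soft_weights(table, mc.assign_bins(table, 4))
corrected = mc.correct_translational(kspace, table, bins)

nmc = mc.recon_nmc(kspace, coils)
bin_imgs = [mc.sense_bin(corrected, bins, coils, b) for b in range(4)]
fields = mc.register_bins(bin_imgs, bins.reference_bin)
mc_img = mc.mocomp_cmra(corrected, bins, coils, fields)

for cl in phantom.centerlines:
    a = mc.vessel_sharpness(nmc, cl, 2.0).sharpness_pct
    b = mc.vessel_sharpness(mc_img, cl, 2.0).sharpness_pct
    print(f"{cl.vessel_id}: sharpness NMC {a:.1f}% -> MC {b:.1f}% "
          f"({100 * (b - a) / a:+.1f}%)")
# Sharpness is normalised so a one-voxel lumen-to-background step is 100%;
# motion correction recovers edge definition the respiratory blur removed.
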