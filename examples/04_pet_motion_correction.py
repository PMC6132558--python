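"""Respiratory-binned PET with reconstruct-transform-average correction.

Simulates count-limited emission data through the breathing phantom,
reconstructs each respiratory bin by attenuation-corrected OSEM (3
iterations, 21 subsets, PSF modelling) with its own warped attenuation
map, averages the bins at end-expiration, and compares the myocardial
signal against the uncorrected reconstruction.
"""

import numpy as np

import mocorr as mc
from mocorr.pet import PETGeometry, Projector, pet_mc, pet_nmc, warp_mumap

phantom = mc.build_phantom(mc.PhantomConfig(matrix=64, defect=mc.DefectSpec()))
trace = mc.simulate_breathing(160, amplitude=10.0, deep_breath_prob=0.0,
                              seed=6)
model = mc.MotionModel(trace)
table = mc.MotionTable(trace.fh_mm, trace.rl_mm, np.ones(160), 0)
bins = mc.assign_bins(table, 4, mc.OutlierRule(method="none"))

geom = PETGeometry()          # 96 angles, 2 mm radial bins, 4.5 mm PSF
sinos, _ = mc.simulate_pet(phantom, model, bins, total_counts=1e6,
                           geom=geom, seed=6)
projector = Projector(geom, phantom.shape)
fields = mc.translation_field_set(bins, phantom.shape, 2.0)

nmc = pet_nmc(sinos, phantom.mu_map, phantom.shape, projector=projector)
mcimg = pet_mc(sinos, warp_mumap(phantom.mu_map, fields), fields,
               phantom.shape, projector=projector)

myo = phantom.myocardium_mask
a, b = nmc.magnitude[myo].mean(), mcimg.magnitude[myo].mean()
print(f"mean myocardial signal: NMC {a:.3f} -> MC {b:.3f} "
      f"({100 * (b - a) / a:+.1f}%)")
pm = mc.relative_increase(
    mc.polar_map_17(mcimg, phantom.lv_geometry, myo, 2.0),
    mc.polar_map_17(nmc, phantom.lv_geometry, myo, 2.0))
print(f"17-segment increase: mean {np.nanmean(pm.values):+.1f}%, "
      f"max {np.nanmax(pm.values):+.1f}%")
# Correcting both the emission data (per-bin recon + warp) and the
# attenuation-map alignment raises the apparent myocardial uptake that
# respiratory blur and mu-map mismatch had suppressed.
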