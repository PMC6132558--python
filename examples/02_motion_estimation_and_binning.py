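"""Estimate beat-wise respiratory motion from 2D iNAVs and bin the beats.

Simulates 120 heartbeats of 10 mm breathing, generates the per-beat
coronal navigators, registers an apex template to each, and sorts beats
into four equal-count respiratory bins with deep-breath rejection.
"""

import numpy as np

import mocorr as mc

phantom = mc.build_phantom(mc.PhantomConfig(matrix=64))
trace = mc.simulate_breathing(120, amplitude=10.0, deep_breath_prob=0.08,
                              deep_breath_scale=3.0, seed=8)
model = mc.MotionModel(trace)

inavs = mc.simulate_inavs(phantom, model, trace)
table = mc.estimate_translation(
    inavs, mc.default_template(inavs, phantom.lv_geometry))

truth = trace.fh_mm - trace.fh_mm[0]
rmse = np.sqrt(np.mean((table.fh_mm - truth) ** 2))
print(f"FH estimation RMS error: {rmse:.2f} mm over {table.n_beats} beats")

bins = mc.assign_bins(table, n_bins=4)
sizes = [len(bins.members(b)) for b in range(4)]
print(f"bin sizes {sizes}, rejected {int((~bins.accepted).sum())} beats")
print(f"bin centres (mm FH): {np.round(bins.fh_centers, 1)}")
# The estimator tracks the heart to a fraction of the 2 mm voxel; the
# rejected beats are simulated deep breaths beyond the outlier fence;
# bin centres run from end-expiration (~0) toward end-inspiration.
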