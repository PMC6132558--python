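# mocorr

Respiratory motion-corrected whole-heart PET + coronary MR angiography
(CMRA), as a self-contained simulation, reconstruction and analysis
toolkit.

## The problem

Simultaneous PET-MR can show coronary anatomy (CMRA) and myocardial
viability (¹⁸F-FDG PET) in one examination, but free breathing moves the
heart by ~10 mm every few seconds, blurring both modalities and
misaligning the PET attenuation map. The framework implemented here
corrects both datasets with motion estimated once from the MR data
itself:

1. a 2D coronal image navigator (iNAV) acquired every heartbeat gives the
   beat-wise foot–head (FH) and right–left (RL) translation of the heart
   by rigid template registration over the apex;
2. beats are sorted into equal-count respiratory bins from end-expiration
   to end-inspiration, deep breaths are rejected, and every CMRA interleaf
   is corrected to its bin centre by the k-space phase shift
   `exp(-2πi k·Δ/FOV)`;
3. per-bin 3D images are reconstructed by soft-binned iterative SENSE
   (conjugate gradient on the coil-weighted least-squares problem) and
   registered non-rigidly to the end-expiration bin (multi-resolution
   demons), giving dense deformation fields;
4. the fields drive (a) a generalized-matrix motion-compensated CMRA
   reconstruction whose per-bin forward operator is warp → coil → FFT →
   sample, solved by CG with the exact transpose of the warp as adjoint,
   and (b) motion-corrected PET: each bin reconstructed by
   attenuation-corrected OSEM (3 iterations, 21 subsets, PSF modelling)
   with its own warped μ-map, then reconstruct-transform-average back to
   end-expiration.

Everything runs on a synthetic breathing thorax phantom with ground-truth
motion, centerlines and LV geometry, so every stage can be validated
against an oracle. Image quality is scored the way the field does:
visible vessel length, centreline-normalised vessel sharpness (100% = a
one-voxel intensity step at the lumen edge), and AHA 17-segment polar
maps of the relative PET signal change.

## Worked example

```python
import mocorr as mc

report = mc.run_experiment(mc.ExperimentConfig(seed=1))
for k in ("RCA_sharpness_change_pct", "LAD_sharpness_change_pct",
          "pet_myo_change_pct"):
    print(k, round(report.summary[k], 1))
```

prints

```
RCA_sharpness_change_pct 11.6
LAD_sharpness_change_pct 15.2
pet_myo_change_pct 5.9
```

— with 10 mm breathing, motion correction sharpens the RCA and LAD lumen
edges by 12% and 15% and raises the mean myocardial PET signal by ~6%
relative to the uncorrected reconstruction of the same data; at zero
amplitude all changes are within noise of zero, and the gains grow with
breathing amplitude. The `examples/` directory walks through each stage
(phantom, motion estimation, MR correction, PET correction, full
experiment); `mocorr run --seed 1 --out out/` does the same from the
shell, with per-stage subcommands (`mocorr phantom`, `mocorr acquire`,
`mocorr metrics`) for intermediates. Volumes are written as NIfTI, raw
data as HDF5 containers, tables as CSV/JSON; every report carries its
config hash and seed.

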