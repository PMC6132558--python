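# Methods

`mocorr` simulates and reconstructs a free-breathing, simultaneous
whole-heart PET + coronary MR angiography (CMRA) examination in which the
respiratory motion of the heart, estimated once from MR image navigators,
corrects both modalities. Everything runs on a synthetic digital thorax at
desk scale; no external data are required.

## The phantom and its motion

The phantom is a 3D scene of geometric primitives on an isotropic grid
(default 64 voxels of 2 mm): a torso ellipsoid, two lungs, a liver dome, a
spine, and a heart whose left ventricle is a myocardial ring (FDG-avid)
around a bright blood pool, capped by a hemispherical apex. Two epicardial
tubes play the right coronary artery (RCA, with an optional focal
stenosis) and the left anterior descending artery (LAD); their
centerlines and radii are ground truth. Three co-registered volumes are
produced: MR contrast (bright lumen, suppressed myocardium and fat, the
effect of T2-preparation and fat saturation baked in), activity, and a
four-class 511 keV attenuation map (air 0, lung 0.0022, soft tissue
0.0096, bone 0.0120 mm^-1 — standard coefficients for the segmented-μ-map
approach). An angular wedge in the mid-inferior wall with a transmurality
factor models a viability defect.

Axis convention: arrays are `(x=RL, y=AP, z=FH)`, foot–head positive
toward the head; the coronal plane is x–z.

Breathing is sampled at heartbeat times: a `-A·sin^4(phase)` waveform
(the fourth power gives the long end-expiratory plateau of tidal
breathing; the sign puts inspiration toward the feet), slowly varying
period (8% smoothed jitter), optional linear drift, and Bernoulli deep
breaths that scale a beat's excursion. Defaults — 10 mm foot–head
amplitude, right–left = 0.3 × FH, 4 s period, 5% deep-breath probability
at scale 2 — are plausible adult values chosen once; breathing amplitudes
of real patient cohorts vary and these are configuration, not facts.
A beat is flagged as a deep breath when its *oscillatory* excursion
(drift removed) exceeds 1.05 × amplitude; using the raw displacement
would mislabel late beats under drift.

The motion model maps each beat to a rigid translation `(RL, 0, FH)`;
with `nonrigid=True` the translation is modulated by a smooth
superior–inferior gradient (tissue near the diaphragm moves more than the
chest apex), giving a ground-truth non-rigid field proportional to FH.
Warping is trilinear (pull convention) with one deliberate exception: on
the MR signal path, spatially constant translations are applied as exact
Fourier-domain phase ramps. A continuously shifted object sampled on a
k-space grid *is* a circular phase shift, so this is the physically
faithful MR model, and it keeps the simulated data exactly consistent
with the k-space correction operators; the result is kept complex because
a fractionally shifted real image has no Hermitian spectrum at the
Nyquist bin.

## Acquisition

CMRA: fully sampled Cartesian phase-encode grid in the (RL, FH) plane,
readout along AP. The grid is sorted into spiral-like arms by angular
coordinate (equal counts per arm), each arm ordered centre-out, and arm
*i* is acquired at heartbeat *i* as the unused arm nearest *i* × golden
angle. Defaults: 24 lines per interleaf (a mid-diastolic acquisition
window), 8 coils. The union of interleaves covers every grid point
exactly once — the full-sampling invariant the tests enforce. Coil
sensitivities are Gaussian lobes in two rings staggered along z with
gentle phase ramps; encoding power in both phase-encode directions is
what lets the soft-binned SENSE problems invert. Complex Gaussian noise
is added per sample.

iNAV: each heartbeat's coronal projection, truncated to 14 central RL
phase-encode lines (coarse RL, full FH resolution, mirroring the real
navigator's 1 × 21.7 mm² acquired resolution) and interpolated to a 1 mm
display grid. Simulating the navigator by phase-encode truncation of the
projection captures exactly what matters downstream: its registration
behaviour.

PET: a stack-of-2D parallel-beam scanner (96 views over 180°, radial
spacing = voxel size), built as an explicit sparse matrix of ray-driven
bilinear weights so the back-projector is the exact transpose. Per
respiratory bin, activity and μ are warped to the bin-centre state,
attenuation factors `exp(-∫μ dl)` multiply the line integrals, the mean
sinogram is scaled so the bin's expected counts equal its acquisition-time
fraction × total counts (scanner sensitivity is folded into the count
budget), and Poisson noise is drawn. Optional radial Gaussian PSF
(default FWHM 4.5 mm, typical for whole-body PET-MR) enters both
simulation and reconstruction. Randoms and scatter are not modelled.

## Reconstruction

1. **Translation estimation.** An apex-covering template from the
   reference iNAV is located in every iNAV by normalised
   cross-correlation, refined to sub-pixel precision by a separable
   parabolic fit of the correlation peak. Noiseless 10 mm breathing is
   recovered with ≈0.25 mm RMS error.
2. **Binning and k-space correction.** Deep breaths are rejected by a
   Tukey fence (1.5 × IQR beyond the quartiles — one-sided in effect,
   since breathing has no expiratory tail); the accepted beats are cut
   into equal-count bins ordered from end-expiration (the dense end of
   the trace, identified from the quartile asymmetry) toward
   end-inspiration. Each interleaf is corrected to its bin centre
   (median FH/RL of members) by the Fourier-shift phase
   `exp(-2πi(k·Δ)/FOV)`. Soft gating replaces hard membership with
   Gaussian weights (default width = half the bin-centre spacing),
   renormalised per beat; width → 0 recovers hard binning.
3. **Per-bin SENSE.** Each bin image solves the weighted least-squares
   problem (weights = that bin's soft weights spread onto the sampled
   points) by conjugate gradient on the normal equations, Jacobi
   preconditioned by the coil root-sum-of-squares; defaults 15 iterations
   or relative residual 1e-6. Plain CG guarantees a monotone A-norm
   error, not a monotone residual 2-norm, so the tests assert the final
   residual is the minimum rather than strict monotonicity.
4. **Bin-to-bin registration.** Multi-resolution (shrink 4/2/1)
   fast-symmetric-forces demons on magnitude images, smoothing σ = 2 mm.
   Fields are stored in *pull* convention: `bin(v) ≈ ref(v + f(v))`; the
   phantom's ground-truth object displacement is the negation of the
   pull field for pure translations. A worsened similarity metric flags
   the bin but the field is still returned.
5. **Motion-compensated CMRA.** The generalized-matrix forward operator
   per bin is warp → coil weighting → FFT → sampling with the bin's
   weights; the joint least-squares problem over bins is solved by CG.
   The warp adjoint is the transpose of the trilinear interpolation
   matrix (not the inverse warp) — exact adjointness is what CG needs.
   Spatially constant fields use an exact unitary spectral-shift operator
   instead of interpolation, which is both exactly adjoint and
   attenuation-free; with ground-truth translation fields the MC
   reconstruction then matches the static phantom to ≈1%.
6. **PET.** Per-bin attenuation-corrected OSEM (defaults 3 iterations,
   21 round-robin angle subsets, reduced with a warning if fewer angles
   exist; uniform positive start; zero-sensitivity voxels masked) with
   that bin's warped μ-map, followed by reconstruct-transform-average:
   each bin image is divided by its time fraction (a count-rate image),
   warped to end-expiration through the fixed-point inverse of the pull
   field (tolerance 0.1 voxel), and averaged with equal weights. The
   uncorrected comparator is OSEM on the un-binned sum sinogram with the
   end-expiration μ-map, likewise rate-normalised.

## Metrics

**Vessel sharpness** samples two profiles perpendicular to the local
centerline direction at 0.25-voxel steps (linear interpolation),
takes the maximum absolute central-difference derivative per edge, scales
by one voxel and divides by the centreline intensity: an ideal one-voxel
lumen-to-zero step scores exactly 100%. **Visible length** is the arc
length of the longest contiguous run from the vessel origin where the
centreline-to-background contrast (background = median on a ring at
radius + 4 mm) exceeds 1.5, bridging dips shorter than 3 points.
**Polar maps** partition the ground-truth myocardial mask into the AHA
17 segments (basal/mid/apical thirds of the long axis with 6/6/4
circumferential sectors, zero angle at the anterior wall,
counterclockwise seen from the apex; the apex cap is segment 17) and
average the image in each. **Relative increase** is
`100·(MC − NMC)/NMC` per segment. Ground-truth centerlines and LV
geometry are used deliberately: this isolates reconstruction quality
from tracker quality.

## Error metrics and tolerances

MR consistency checks use Euclidean-normalised RMSE. PET equivalence
checks normalise the RMSE by the reference's peak value instead: emission
activity occupies a small fraction of the volume, and at 1e6 counts the
per-voxel OSEM noise dominates a Euclidean norm regardless of motion, so
peak normalisation is what makes a "Poisson-driven" few-percent tolerance
expressible. At 1e6 counts the static binned-RTA vs un-binned comparison
measures ≈1% peak-NRMSE.

## What the simulation does and does not show

The generator reproduces the mechanisms the correction relies on:
beat-wise translational heart motion observable in a coronal navigator,
equal-count respiratory statistics with deep-breath outliers, count
splitting across bins, and attenuation–emission misalignment. It omits
cardiac contraction, through-plane and bulk motion, fat/water chemistry,
scatter and randoms, and realistic anatomy; passing tests therefore
demonstrate the correctness of the estimation/correction machinery, not
clinical image quality. Quantities measured at desk scale (e.g. percent
sharpness gain) are expected to match clinical reports in direction and
rough magnitude, not numerically — visible-length gains in particular
require distal-vessel dropout that a 64^3 phantom with 2.5 mm vessels
reproduces only weakly. At small amplitudes (≤5 mm) the PET benefit is
within noise and can be slightly negative: each bin holds a quarter of
the counts, and the known bias of reconstruct-then-average at low counts
offsets the small blur reduction; the MR sharpness benefit remains
monotone in amplitude.

## Problem sizes

Tests run at 32³ (unit) and 64³ (integration/acceptance) with 2 mm
voxels; the canonical experiment (171 heartbeats, 8 coils, 4 bins, 1e6
counts) completes in about a minute on one CPU, and the four-amplitude
benefit sweep in about five.
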