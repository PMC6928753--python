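# Methods

This note documents the models, conventions and numerical choices behind
`npk3d`, and what the synthetic test scenes do and do not establish about
real acquisitions.

## Coordinate and pixel conventions

The depth camera frame has x right, y up, z forward (into the scene). Pixel
index `i` is the column and `j` the row; back-projection is
x = (i − cₓ)·z/fₓ, y = −(j − c_y)·z/f_y, z = Depth(i,j)/1000 m, so larger row
indices map to lower y (image origin top-left). Depth value 0 means *missing*,
never distance zero. Intrinsics default to Kinect-v2-like values
(512 × 424 px, fₓ = f_y = 365, cₓ = 256, c_y = 212).

Coordinates are carried in meters; Hausdorff statistics are reported in
centimeters, the customary reporting unit for canopy-scale reconstruction
error.

## Spectral registration

The spectral imager and the depth camera are rigidly mounted, so a single
similarity transform (column shift x₀, row shift y₀, rotation θ₀, isotropic
scale σ) relates their images, and the same transform is applied to every
wavelength band. The transform scales/rotates about the image center first
and translates second.

* **Translation**: peak of the inverse FFT of the normalized cross-power
  spectrum. Exact for circular integer shifts; an optional parabolic fit
  around the peak provides subpixel refinement (off by default — pixel-level
  accuracy suffices for 512 × 424 depth frames).
* **Rotation/scale**: both images are windowed (raised-cosine/Hann) to
  suppress wrap-around edges; the log-compressed, fft-shifted magnitude
  spectra are resampled to log-polar coordinates (720 angular bins = 0.5°,
  400 logarithmic radial bins over [1, min(m,n)/2]) and phase-correlated with
  20× upsampling. Log compression keeps the DC-dominated spectrum from
  swamping the texture. The magnitude spectrum's inherent 180° ambiguity is
  resolved by registering both candidates end-to-end and keeping the one
  whose warped image has the higher spatial (Pearson) correlation with the
  fixed image over the valid overlap — the raw phase-correlation peak alone
  is unreliable for near-point-symmetric content.
* **Resampling**: bilinear. Pixels whose source falls outside the moving
  image (or on invalid input pixels) become *invalid* in the output mask
  rather than zero-filled reflectance; validity is propagated with the same
  bilinear warp and a conservative >0.999 threshold, which erodes roughly one
  pixel at every mask boundary per warp. On thin structures (leaf edges) this
  erosion is the dominant cause of spectral-coverage loss.
* **RGB graying** uses ITU-R BT.601 luma weights (0.299, 0.587, 0.114)
  throughout.

Measured on seeded synthetic pairs (256² anisotropic texture, composite
transforms up to ±15 px, ±25°, scale 0.85–1.2): translation exact, rotation
within 0.2°, scale within 0.3 % — comfortably inside the 1° / 2 % working
tolerance of the pipeline.

## Turntable self-calibration

A 180° rotation maps each sticker centroid to its antipode across the axis,
so the midpoint of each before/after pair lies on the axis line; with both
stickers on the turntable disc (a plane perpendicular to the axis) the two
midpoints coincide at the axis center M. The direction P is the normalized
cross product of the two chords, signed so its y-component (camera up) is
positive. Guards: each color gate must pass ≥ 3 points; the chords must
subtend ≥ 5°; the midpoints must agree within 5 mm (configurable — the
midpoints separate along the axis if the stickers are mounted at different
heights). Sticker colors are gated in RGB with configurable per-channel
bounds (yellow: R,G ≥ 150, B ≤ 100; red: R ≥ 150, G,B ≤ 100). Calibrations
persist to JSON and are reused while the camera–turntable geometry is fixed.

**Axis tilt angles.** The printed form of the two tilt rotations is
typographically ambiguous in sign, so the package defines them
constructively: β = atan2(a, b) rotates about Z to null the x-component,
then α = atan2(c, √(a²+b²)) rotates about X to null the z-component;
`axis_alignment_rotation(α, β)` maps P exactly onto +Y (property-tested on
1000 random directions to 1e−9). The view transform is then
coords′ = R_y(−γ)·A·(coords − M), γ being the turntable angle of the view;
because A is a proper rotation taking the axis onto +Y, R_y(−γ)·A exactly
undoes a physical rotation of +γ about the axis.

## ICP refinement

Point-to-point ICP with an SVD (Kabsch) update. Defaults: max 50 iterations,
convergence when the inlier RMSE improves by < 1e−6 m, correspondence cutoff
1 cm. On top of the cutoff, only the closest 80 % of inlier correspondences
drive each update (trimmed ICP): turntable views overlap only partially, and
untrimmed nearest-neighbor matches from non-overlapping surface pull the
alignment measurably (noise-free reconstruction error grew from 0.068 to
≈ 0.09 cm without trimming). Views are fused sequentially in acquisition
order, each new view refined against the running fused cloud; spectral
attributes ride along unchanged. Optional voxel downsampling is off by
default. The fitted transform, inlier fitness and inlier RMSE are reported.

## Quality metrics

* D = 1 − Σ|M−F| / (m·n·255) on 8-bit-scaled images over the registered
  region (both images cropped identically; the region choice is a parameter,
  default the full registered frame).
* C = 100 · |F₂ ∧ M₂| / |F₂| with F₂ the reference (depth-ROI) binary mask.
* HD: directed nearest-neighbor Euclidean distance set (KD-tree, verified
  exactly equal to the brute-force all-pairs scan). Not symmetric; the
  maximum equals the classical directed Hausdorff distance. Statistics use
  the *population* (divide-by-N) standard deviation. Bin edges: (0, 0.1],
  (0.1, 0.3], (0.3, 0.6], (0.6, 1.0], (1.0, ∞) cm, zeros counted in the
  first bin; proportions sum to 100 %.
* When reconstruction and reference scan live in different frames, ≥ 3
  non-collinear manually selected landmark pairs feed a least-squares
  (Kabsch) rigid alignment of the reference before the distance computation.

## Wavelength selection (PCA-CC-RF)

Preprocessing: per-curve Gaussian smoothing with kernel width 6 samples
(σ = width/3, reflective boundary — "window 6" is interpreted as the kernel
width, exposed in config), then removal of the six near-infrared bands
corrupted by the depth sensor's active illumination (841.42–868.65 nm;
128 → 122 bands).

Evidence sources: PCA on centered (not variance-scaled — reflectance shares
units) spectra, with candidate wavelengths at local extrema of the
contribution-weighted aggregate |loading| profile; per-wavelength Pearson
correlation with the nutrient (zero-variance columns are flagged and set to
r = 0); and the random frog.

**Random frog.** Reversible-jump subset search with a PLS inner model (≤ 5
latent variables): each iteration proposes a subset size from
N(q, 0.3q); shrinking keeps the top |PLS coefficient| variables, growing
samples 3× the deficit from the complement and re-ranks. A candidate is
accepted when its 4-fold cross-validated RMSE is lower, else with probability
0.1 · RMSE/RMSE*. The selection probability of a wavelength is the fraction
of iterations whose accepted subset contains it; runs are deterministic under
a fixed seed, with 1000 iterations and an initial subset of 8 by default.
Under a null (pure-noise) response the search deterministically latches onto
the spuriously best predictors of that particular draw, so the meaningful
null property — and the one tested — is that the top-ranked wavelengths are
not reproducible across independent noise draws.

**Combination rule.** Local strict peaks of the selection probability are
candidates where the spectral neighborhood is coherent (adjacent-band
autocorrelation ≥ 0.9 by default; smooth measured reflectance easily clears
this, while deliberately decorrelated synthetic fixtures use a lower
threshold). Candidates lacking both correlation evidence (|r| ≥ 0.2) and a
PCA loading peak within 12 nm are removed; configured PCA-CC supplement
wavelengths are added and flagged as such. Per-wavelength provenance
(RF-peak / PCA-CC-supplement / removed) is part of the result.

## NPK regression

All three learners standardize features and target internally.

* **BPANN**: three-layer feedforward net, 15 tanh hidden nodes, linear
  output, L-BFGS (quasi-Newton) training, ≤ 500 iterations, goal 1e−4,
  seeded initialization.
* **SVMR**: epsilon-SVR, Gaussian kernel with kernel scale 0.56
  (γ = 1/0.56²; the "fine Gaussian" preset √P/4 for P = 5 features).
  "Automatic" box constraint = iqr(y)/1.349 on the standardized target;
  epsilon = box/10. This kernel scale makes the SVR a *local* interpolator:
  it performs well only when calibration samples densely cover the feature
  manifold, and degrades on designs with well-separated dose clusters — the
  same pattern visible in the original study, where SVMR trails the other
  two learners throughout.
* **GPR**: constant mean, isotropic rational-quadratic kernel plus a white
  noise term, hyperparameters by marginal-likelihood optimization with 3
  seeded restarts.

Evaluation: Rc²/Rp² are squared Pearson correlations between measured and
predicted values (the 1 − SSE/SST convention is available via a flag; for
constant predictions R² is reported as NaN rather than a misleading number).
RMSEC/RMSEP are root-mean-square residuals on the calibration/prediction
sets. RE — not given a formula in most reports — is defined here as the mean
absolute relative error over the prediction set, mean(|ŷ−y|/y)·100 %, which
requires strictly nonzero targets. The default split is 42 calibration / 18
prediction samples via a seeded shuffle, unstratified. `run_model_matrix`
fits the full nutrient × learner × input-source grid (3 × 3 × 5 = 45 models
for four single views plus the fused cloud).

Chemistry: the Kjeldahl, molybdenum-antimony and flame-AAS mass-fraction
formulas are implemented exactly as printed, in g/100 g, with guards on
nonpositive denominators.

## Synthetic scenes: what they emulate and what they do not

`make_plant_cloud` builds a rigid parametric plant — cylindrical stem,
ellipsoidal leaf patches with a slight bend, cylindrical pot — sampled at
2·10⁶ points/m² (≈ 0.7 mm spacing, emulating a dense handheld-scanner
reference model). Leaf/stem points carry a vegetation-like reflectance curve
(green bump, red edge); pot points carry *no* reflectance, mirroring a
spectral imager whose footprint excludes the pot.

`render_views` projects the rotated cloud through the pinhole model with a
z-buffer whose per-pixel depth is not the raw nearest splat but the visible
surface depth along the pixel-center ray, obtained from a least-squares local
plane fit (neighbors within 1.5 px and within 8 mm of the front depth,
clamped to that band). A 1-pixel splat would leave a lateral quantization
error of 0.5 px·z/f ≈ 1.6 mm at 1.2 m — larger than the 1 mm depth
quantization itself — whereas the plane-fit render keeps back-projected
points on the true surface up to quantization. Depth maps get Gaussian noise
(default σ = 2 mm, a consumer-depth-camera figure) and 1 mm quantization;
attribute channels take the nearest projecting point. The spectral cube is
corrupted by the inverse of the scene's known registration transform, so the
registration stage can be validated round-trip. Sticker frames for
calibration are emitted at 0° and an exact 180°.

Not modeled: radiometry/BRDF, sensor-specific depth distortion, non-rigid
motion (leaf/stem shake during rotation — a known error source for real
turntable rigs), occlusion-dependent reflectance bias. Passing the synthetic
end-to-end bound (noise-free HD_avg ≈ 0.07 cm < the 0.1 cm quantization;
≈ 0.14 cm at 2 mm noise) therefore validates the geometry and code paths,
not the full error budget of a physical rig, whose reported reconstruction
errors are several times larger.

The nutrient generator draws five fertilizer dose levels (25–200 % of
standard, equal group sizes; 60 samples ⇒ 12 per dose), maps dose to each
nutrient by a saturating response with 4 % per-plant jitter (N up to
~52 mg/g, P ~8.5, K ~46 — greenhouse-tomato leaf ranges), and adds
nutrient-linked Gaussian signatures (amplitude 0.03, width 9 nm) at planted
wavelengths on a 128-band grid containing the six interference bands at
their exact nominal positions. Two leaner fixtures serve validation:
`make_planted_signal_dataset` (decorrelated band noise, response linear in
five well-separated columns — identifiable for selection-recovery tests) and
`make_linear_calibration_dataset` (evenly spaced rank-1 calibration
gradient — the standard design for verifying that a regression
implementation recovers a clean linear response; the dense even spacing is
what the fine-scale SVR needs, see above).

## Problem sizes and determinism

Synthetic validation runs use: 256² images (20 transform-recovery pairs),
4-view scenes of ≈ 120 k ground-truth points (≈ 14 k reconstructed), 100
noisy calibration trials, 20 random-frog runs of 1000 iterations on
200 × 128 spectra, and 60-sample 42/18 regression splits. Every stochastic
stage takes an explicit seed; the CLI threads one top-level seed through all
stages, and rerunning any command with the same inputs and seed reproduces
byte-identical reports.
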