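# Methods

## Scope and data model

dosekit operates on real-valued 3D grids with spacing/origin metadata
(`VolumetricImage`); the same container carries SPECT counts, absorbed dose
(Gy) and attenuation coefficients (mm⁻¹). Organ segmentations live in a
single integer label volume (`SegmentationSet`) whose primitive labels are
whole-normal-liver (WNL), tumour, lungs, kidneys, stomach and remaining
body; composite regions (whole liver WL = WNL ∪ tumour, body) are derived,
so the set identities WNL = WL \ tumour and region ⊆ body hold exactly, and
survive nearest-neighbour resampling by construction. NIfTI-1 is the
canonical storage format (RAS, identity direction unless provided);
MetaImage is accepted. Voxel indices are 0-based with
world = origin + index · spacing. Dose/count resampling treats values as
concentrations (intensive, the right convention for Gy); an extensive mode
that preserves totals (counts) is available behind a flag.

## Calibration

Two calibrations are implemented. The *phantom conversion factor* follows
the uniform-cylinder protocol (6200 mL, 605.33 MBq by default): the central
ROI is realised by isotropic binary erosion of the phantom mask until its
volume is at most the requested fraction (70 % default; ties broken toward
the smaller ROI), and CF = count rate in the ROI divided by the activity
its volume contains. The CF is computed and reported but *not* used in
patient dosimetry: the dosimetry chain uses the *patient-relative* scale
`A_inj / Σ_WL counts`, which is invariant to acquisition time and scanner
sensitivity and avoids any geometric mismatch between a calibration source
and the patient's anatomy. Decay correction between assay and scan, dead
time and partial-volume effects are the caller's responsibility.

## LDM dosimetry

Local energy deposition with T½ = 64.1 h, Ē = 0.93 MeV, ρ = 1.05 g/cm³
(uniform density everywhere, including lungs; a density-map hook exists but
defaults off). Some compilations quote Ē ≈ 0.937 MeV for ⁹⁰Y; the constant
is config-overridable. The WL-derived scale is applied image-wide, so lungs,
kidneys and stomach receive doses from the same map. Exact invariants
(tested at 1e-10 relative): WL energy conservation, locality (dose at a
voxel depends only on its own counts and the WL sum), and the closed form
49.6 Gy for 1 GBq in 1 kg.

## Synthetic phantoms

Patient data cannot be redistributed, so the chain is exercised on
ellipsoidal digital phantoms: body, liver (tumour-bearing), lungs, kidneys,
stomach, with piecewise-constant activity — liver 1.0, tumour
`uptake_ratio` (default 5, tumour-avid glass-microsphere SIRT), faint body
background 0.02, lung shunt 0.03. Geometry is parameterised in fractions of
the grid extent (the tumour in mm) and jittered per seed so cohorts are
heterogeneous. Defaults mirror the clinical acquisition: 128³ grid at
4.795 mm isotropic; the desk profile uses 48³ (≈230 mm field of view) with
0.25 GBq injected, giving ≈70 Gy mean liver dose and 200–400 Gy tumour
doses — clinically plausible magnitudes. The tumour centre sits on the deep
(body-centre) side of the liver, which is what makes the interior tumour
more attenuated than the liver average.

Degradations:

* **Attenuation** multiplies each voxel by the mean over a fan of in-plane
  directions (16 by default, spanning 180° like a 180° SPECT arc; 64
  available) of exp(−∫μ dl) along the ray to the body surface, computed by
  rotate–cumulate–rotate-back line integrals with half-voxel centring.
  μ_soft = 0.011, μ_lung = 0.003, μ_bone = 0.017 mm⁻¹ are effective
  broad-spectrum bremsstrahlung stand-in constants (config-overridable).
  The operation never increases a voxel and is the identity at μ = 0.
* **Scatter** is count-conserving redistribution
  (1−f)·x + f·G(x) with f = 0.35 (photopeak-window scatter is 30–40 %
  clinically) and a 30 mm FWHM Gaussian — deliberately much broader than a
  ~9 mm reconstruction filter so scatter and resolution effects stay
  distinguishable. Symmetric boundary handling keeps the global sum exact.
* **Poisson noise** is applied to count maps (2×10⁶ expected total by
  default), where counting noise physically enters, before calibration.

States: ASC = true activity, AC = scatter-degraded only (attenuation
"already corrected"), NC = attenuation applied on top of scatter (the
scanner cannot scatter-correct without attenuation-correcting). After
patient-relative calibration all three dose maps share the WL energy, so
the triplet differs only spatially: the interior tumour is underdosed and
the WNL overdosed without scatter correction, and surface regions
relatively overdosed without attenuation correction — the bias pattern the
learned corrections remove. What the phantoms do **not** emulate: OSEM
reconstruction artefacts, collimator–detector response, metal implants and
other high-density objects, breathing motion, and real anatomical shape
variability; passing tests therefore demonstrate the correctness of the
chain and the learnability of the synthetic degradations, not clinical
performance.

## Correction engine

Tasks bind correction states — AC: NC→AC, SC: AC→ASC, ASC: NC→ASC — and
every dose map carries its state, so feeding a mismatched map raises
(total contract enforcement). Training follows the 5-fold protocol: cases
are shuffled under a seed and dealt round-robin into folds whose sizes
differ by at most one; one model per fold trains on the other folds with L1
loss on patches of the normalised maps (fixed 0–200 Gy scale *without
clipping*: 400 Gy normalises to 2.0, so the mapping is exactly invertible);
inference averages the fold models voxelwise (running-mean formulation, so
an ensemble of identical members reproduces a single member bitwise) with
sliding-window tiling (training patch size, 50 % overlap, uniform blend
weights). Augmentation is restricted to 90° rotations and axis flips,
applied identically to both members of a pair — deformable augmentation
would corrupt the quantitative dose values. Defaults: 64³ patches, Adam
with learning rate 1e-3, weight decay 1e-4, batch 2, 200 epochs, dropout
0.1; the desk profile uses 32³ patches and 10 epochs. Per-fold training and
validation L1 curves are logged in the ensemble bundle. Count-domain
training is reachable by feeding count maps with a different normalisation
constant; dose-domain is the default because Gy values carry a consistent
physical meaning across scanners.

The default regressor is a *local-feature MLP*: a voxelwise residual
multilayer perceptron (two hidden layers of 16 ReLU units, zero-initialised
output) over context features precomputed on the full normalised input
volume — the value, Gaussian-smoothed copies, the in-plane depth below the
body surface, and first-order physics priors: a Chang-style
attenuation-factor estimate (mean in-plane Beer–Lambert survival through
the thresholded body contour at uniform soft-tissue μ) with its re-gained
image, and first-order scatter deconvolutions (x − f·G(x))/(1−f). The
linear output skip is warm-started by a closed-form ridge regression on a
voxel sample of the fold's training cases; Adam refines all parameters from
there, which cuts the CPU epochs needed by an order of magnitude relative
to a cold start. Because the learned map is voxelwise given
globally-computed features, sliding-window inference is exactly seam-free.
The architecture is pluggable behind a featurise/train-step/predict-patch
contract, so heavier volumetric networks can be dropped in without touching
the training or inference protocol. Predictions are denormalised and
clamped at 0 (absorbed dose is non-negative).

## Evaluation battery

Voxel metrics over a mask (default: body, to avoid rewarding agreement on
empty background): ME, MAE, MSE, RMSE; PSNR with the in-mask reference
maximum as data range; SSIM with a 7³ uniform window, k₁ = 0.01,
k₂ = 0.03 on the per-volume range, sample-covariance normalisation,
computed over the mask bounding box (cross-checked against scikit-image to
1e-6); RE and RAE in the global sum-ratio form (the per-voxel form explodes
at near-zero reference voxels; a floored per-voxel variant is available by
flag). Every report records the conventions used. Joint-histogram fits are
ordinary least squares on the raw voxel pairs (the 2D histogram is for
display only).

Gamma analysis samples the evaluated dose trilinearly on a ⅓-voxel
refinement grid at all offsets within ceil(2·DTA) mm, visited in order of
increasing distance with early termination; γ is capped at 2, capped voxels
counting as failures (pass rates are cap-independent). DD normalisation is
global (reference maximum) by default — the dominant convention when
unstated — with a local mode available; no low-dose threshold by default
(whole-image pass rates around 97 % for uncorrected inputs imply background
voxels are included), configurable otherwise. An exhaustive brute-force
implementation serves as the oracle in the tests (equivalence at 1e-9 on
small volumes).

Organ dosimetry: MAD (in-region mean), across-voxel SD, region
RE = 100·(MAD_pred − MAD_ref)/MAD_ref (MAD-ratio form, scale-stable),
RAE = |RE|, median shift defined as the difference of medians (not the
median of differences). Cumulative DVHs on a regular 0.5 Gy grid satisfy
V(0) = 100 %, monotone non-increase and the layer-cake identity
∫V(D)/100 dD = MAD within one bin width (property-tested). Cohort MAD
comparisons use the two-sided Mann–Whitney U (exact for small untied
samples, tie-corrected normal approximation otherwise), cross-checked
against brute-force enumeration of rank arrangements.

## Numerical choices and degenerate inputs

* Body contour: threshold at 1 % of the 99.9th-percentile value, largest
  26-connected component, one closing pass with a 1-voxel ball.
* Resampling aligns grids at the shared origin and samples with trilinear
  (continuous) or nearest (labels) interpolation; a constant field is
  preserved exactly in the interior.
* Empty regions are skipped with a warning; zero reference sums make
  relative metrics undefined (error at voxel level, NaN at region level);
  all-identical rank-sum pools warn and report p = 1.
* PSNR of identical maps is reported as +inf.
* All stochastic stages (phantom jitter, Poisson sampling, fold shuffling,
  patch sampling, dropout) derive from explicit seeds; fixed seeds give
  bit-identical phantoms and reproducible training histories.

## Problem sizes

The shipped desk profile — 12 phantoms at 48³, 32³ patches, 10 epochs,
5 folds — was sized so a full end-to-end run (simulation, three task
trainings, ensemble inference, the complete evaluation battery including
one gamma case per task) completes in minutes on a single CPU while leaving
clear daylight between the corrected and uncorrected error levels. The
`full_profile` configuration records the full-scale protocol (190 cases,
128³, 64³ patches, 200 epochs) for use on appropriately sized hardware.

## Known limitations

* The degradation model is a physics stand-in, not a reconstruction
  simulator; learned corrections trained on it do not transfer to clinical
  data.
* The default regressor is intentionally small; it exploits the smoothness
  of the synthetic degradations and would underfit pathologies like metal
  artefacts.
* Attenuation line integrals use interpolating rotations; small
  interpolation residue (< 1e-3 of the factor) exists away from axis-aligned
  directions, which is why the exactness tests use a single axis-aligned
  direction.
* Organ SDs are across voxels at case level; cohort tables aggregate
  across cases separately — both are labelled in the outputs.
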