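# Methods

`datquant` implements an automatic semiquantitative analysis pipeline for
dopamine-transporter (DAT) brain SPECT, together with the synthetic data
needed to exercise and validate every stage without access to clinical
scans. This note records the models, the tunable parameters that matter,
the numerical choices, and what the synthetic experiments do and do not
demonstrate.

## The quantification model

DAT tracers (TRODAT-like tropanes, FP-CIT) concentrate in the striatum
(caudate plus putamen); the occipital lobe has negligible DAT density and
serves as the background reference. The endpoint is the specific uptake
ratio

    SUR = (mean target − mean background) / mean background,

computed over regions of interest. Two ROI strategies are implemented:

* **manual-slab emulation** — the three transverse slices with the
  greatest total activity are summed into a single 2D image and
  user-supplied striatal and occipital masks are applied, mirroring the
  slab protocol used for hand-drawn ROIs. 3D masks are collapsed to the
  footprint of the structure *within the selected slices*, which is what
  an operator outlining the visible uptake would draw. Slice ties break
  toward the lower slice index.
* **automatic** — the tracer volume is spatially normalized to a template
  in MNI space and integer-label atlas regions (caudate, putamen,
  occipital; striatum = caudate ∪ putamen, background = left+right
  occipital pooled) are applied on the standard 2 mm grid. Zero-filled
  out-of-field voxels introduced by reslicing are excluded from ROI means
  by default so they cannot dilute the occipital reference.

SUR is a ratio, hence exactly invariant under global intensity scaling;
it can legitimately be negative when the (mis-)selected target region has
lower uptake than the reference — the signature of a failed
normalization.

## Spatial normalization

Normalization follows the classical template-matching formulation: find
the 12-parameter affine `M` (translate ∘ rotate ∘ shear ∘ zoom) and a
low-frequency displacement field `u` minimizing the mean squared
difference between template `g` and the intensity-scaled resampled
source,

    E = Σ_x ( g(x) − s·f(M(x + u(x))) )².

* The **affine** stage is damped Gauss–Newton with analytic
  image-gradient Jacobians and the global intensity scale `s` profiled in
  closed form every iteration; steps are only accepted if the objective
  decreases, so the logged trace is monotone non-increasing.
  Coarse-to-fine working blur: 8 mm then 4 mm FWHM on working copies, at
  a 4 mm working sampling grid by default.
* The **warp** `u` is spanned by the lowest-frequency separable cosine
  (DCT) basis over the template bounding box, 25 mm cutoff; on the
  standard box [−90,−126,−72; 90,90,108] this yields a 7×9×7 basis per
  displacement component. Coefficients are fitted by regularized linear
  least squares (at most 16 outer iterations, early convergence at
  relative objective change < 1e-5). The normal equations are assembled
  through separable Kronecker contractions rather than an explicit
  (N × 1323) Jacobian, which keeps the solve exact and fast.
* The **penalty** is membrane-energy-like: each coefficient is weighted
  by its squared spatial frequency (plus a small floor of 1e-3 of the
  mean weight, so that even the constant basis functions are driven to
  zero in the infinite-regularization limit; constant displacement is the
  affine's job). The user-facing regularization weight (default 1)
  multiplies an internal scale that equates the average penalty curvature
  per coefficient with the average data curvature; this internal constant
  is `reg_internal_scale = 1.0` in `RegistrationConfig`. The choice keeps
  warps gentle on well-matched images while still permitting the
  characteristic misbehavior on grossly mismatched intensity
  distributions (see "failure mode" below).
* **Reslicing** is trilinear with zero fill outside the source field of
  view, and intensities are *not* modulated by the local Jacobian: a
  uniform image stays uniform under any estimated warp ("preserve
  concentrations" off).
* **Rigid coregistration** (6 parameters) for multimodal tracer↔T1 pairs
  maximizes normalized mutual information on a 64×64 joint histogram
  (lightly smoothed for a continuous search landscape) with Powell's
  derivative-free method; rotations are internally rescaled so Powell's
  steps are comparable across parameters. A mean-squared-difference mode
  (Gauss–Newton with zooms/shears frozen) is available for same-modality
  work.

Estimated parameters (affine, DCT coefficients, grids, intensity scale)
serialize to JSON and reapply losslessly — the functional analog of an
SPM `*_sn.mat` file.

## Template construction

Two build procedures, matching how tracer-specific templates are made in
practice:

* **Iterative (two-pass)**: normalize every healthy tracer volume to a
  seed template (typically a generic perfusion template), average the
  normalized volumes into a preliminary template, re-normalize the
  *original* volumes to that preliminary template, average again, smooth
  at 8 mm FWHM. The second pass matters because the interim target now
  has the tracer's own uptake distribution. No intermediate smoothing is
  applied to the preliminary template (only the final one); this is a
  deliberate default where practice varies.
* **Indirect (anatomy transfer)**: for subjects with a paired T1-like
  scan — rigidly coregister tracer → T1, normalize T1 → T1 template,
  reslice the coregistered tracer through the T1's normalization
  parameters, average, smooth at 8 mm. The anatomical channel carries far
  more spatial information than the tracer pattern, so this template
  sits most accurately in standard space.

Per-subject normalization failures are excluded with a logged reason
rather than aborting a batch build; averaging is an unweighted mean.

## Synthetic data

All validation runs on generated inputs:

* **Striatal phantom** — a head-shaped uniform background with four
  equal-volume ellipsoidal striatal compartments: both caudate nuclei at
  3× background, right putamen 2×, left putamen 1×. Ellipsoid centers sit
  on the 2 mm MNI lattice, so mirrored/translated compartments occupy
  *exactly* equal voxel counts on the default grid and the closed-form
  SURs hold to machine precision: caudate 2.0, right putamen 1.0, left
  putamen 0.0, volume-weighted whole striatum (3+3+2+1)/4 − 1 = 1.25.
  Optional degradation: Gaussian PSF blur (emulating post-reconstruction
  resolution) and Gaussian or Poisson count noise. Reconstruction physics
  (filtered backprojection, attenuation correction) is deliberately not
  simulated — the validation logic only needs post-reconstruction
  volumes.
* **Synthetic subjects** — a striatum-dominant tracer volume (healthy:
  caudate 3×, putamen 2.5× background; ventricular CSF at 0.25×) plus a
  pseudo-T1 channel (bright scalp shell, mid-intensity parenchyma, dark
  ventricles). Disease is a severity parameter in [0, 1] that removes
  specific uptake — fully from the putamen, half from the caudate at
  severity 1 — emulating the posterior-dominant dopaminergic loss
  pattern. Both channels share a random rigid+zoom head misalignment
  (|t| ≤ 10 mm, |r| ≤ 0.1 rad, zooms 0.95–1.05), and the tracer carries a
  small extra rigid offset relative to the T1 (≤ 4 mm, ≤ 0.04 rad) that
  rigid coregistration must recover. Defaults: 8 mm PSF, 2% relative
  Gaussian noise. Every generative transform is recorded, so registration
  accuracy is scored exactly.
* **Perfusion-like template** — a cortex-dominant pattern (bright
  cortical shell, dimmer interior, brain-only outline at 86% of the head
  surface), deliberately mismatched to striatum-dominant tracer images.
* **Cohorts** — reproducible subject lists with per-subject derived
  seeds; healthy members at severity 0, patients drawn uniformly from
  [0.3, 0.9].

### The mismatched-template failure mode

Normalizing a striatum-dominant, scalp-bearing tracer image against a
cortex-dominant, brain-outlined template misestimates the spatial
transform: the scalp is pulled toward the bright cortical shell and the
warp drags the hot striatum outward. The atlas striatal ROI then samples
background and ventricular CSF, lowering the SUR — to below zero for
severely affected subjects, since their striatal signal barely exceeds
background to begin with. The two-pass iterative template inherits a
(consistent) spatial bias from its first pass through the mismatched
seed but regains tracer-typical contrast, so it quantifies better than
the mismatched template and worse than the anatomy-transfer template.
This ordering — indirect ≥ iterative ≥ mismatched on both correlation
with ground truth and striatal ROI overlap — is the headline property the
acceptance experiment checks.

## Agreement statistics

Paired manual/automatic SUR tables are scored with: percent error
|m − a|/m × 100; per-subject variability |m − a| / ((m + a)/2)
summarized as mean ± sample SD (n − 1; subjects with a zero pair mean are
excluded and listed); Pearson correlation; Bland–Altman differences
taken as manual − automatic with 1.96 SD limits of agreement (so a
systematically higher automatic method shows a negative bias); and the
one-way random-effects ICC(1,1),

    ICC = (MSBS − MSWS) / (MSBS + (k − 1)·MSWS),   k = 2,

returned *unclamped* — negative values are meaningful (between-method
disagreement exceeding between-subject spread) and are reported as-is.
The two-sample t-test is pooled-variance Student's, with Welch available
behind a flag. Tables load from CSV or XLSX with case-insensitive header
matching (manual/mbt/hbt/hmpao) and an explicit column-mapping override.

## Problem sizes and numerical choices

Desk-scale defaults, chosen so the full synthetic study runs on one CPU
in minutes: volumes on the standard 2 mm grid (91×109×91); affine
estimation sampled at 4 mm (6 mm in the cohort pipeline); warp estimation
at the final blur level with 16 iterations (8 in the pipeline);
iterative-template cohort of 6 healthy subjects, 7 tracer/T1 pairs for
the indirect template, comparison cohort of 8 subjects. Convergence:
relative objective change < 1e-5 or parameter step < 1e-4; affine
iteration cap 32. Ill-conditioned warp systems are ridge-stabilized with
a logged warning. Gaussian smoothing uses reflective boundaries so a
constant volume is exactly preserved. On-disk volumes are float32 NIfTI-1
with the sform authoritative; all in-memory arithmetic is double
precision. Ties in hottest-slice selection resolve to the lower index;
degenerate (constant) images are rejected by the registration entry
points rather than silently fitted.

## What the synthetic experiments do not show

The generator uses concentric ellipsoidal anatomy, a spatially uniform
background, and a Gaussian PSF; it does not reproduce scanner-specific
resolution anisotropy, scatter, attenuation artifacts, partial-volume
structure of real cortex, or realistic T1 tissue texture. Passing the
synthetic ordering experiment therefore demonstrates that the *pipeline
mechanics* reproduce the expected template ranking and failure modes, not
that any particular clinical effect size would be obtained on real
scans. Absolute SUR levels depend on the generator's uptake ratios and
PSF and should not be compared against clinical values; only their
orderings, invariances and closed-form cases are asserted. The ICC and
other agreement statistics, by contrast, are exact implementations
verified against independent references to 1e-10.
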