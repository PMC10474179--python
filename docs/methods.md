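# Methods

This note documents the models and procedures the package implements, the
defaults and why they were chosen, what the synthetic generators do and do
not emulate, and the numerical decisions a maintainer should know about.

## The diffusion tensor fit

Single-shell diffusion-weighted signals are modelled by the
Stejskal–Tanner single-tensor equation S(b, g) = S0·exp(−b·gᵀDg), linear
in log-signal. `fit_tensor_wls` solves the log-linear system per voxel by
ordinary least squares, then performs one reweighting pass with weights
equal to the squared predicted signals — the standard weighted-least-
squares variant for DTI, which down-weights strongly attenuated (noisier
in log space) measurements. One pass is used rather than iterating to
convergence; with typical SNR the second iteration changes components far
below the noise floor, and the single-pass scheme keeps the estimator a
closed-form two-stage solve.

Numerical choices:

- Signals are clipped to 1e-6 × the voxel's mean b0 signal before the log
  transform; this avoids −∞ without biasing realistic SNR levels.
- Volumes with b < 50 s/mm² are treated as b0 (the usual tolerance for
  vendor b0 jitter). Fitting requires ≥ 1 b0 volume and ≥ 6 distinct
  diffusion directions (antipodal pairs merged) among ≥ 7 volumes.
- Voxels with no usable signal, or whose weighted normal equations are
  numerically singular, are excluded from the output mask; their count is
  logged and written to the provenance sidecar.
- Fractional anisotropy is computed from eigenvalues clipped at zero (so
  FA stays in [0, 1] for slightly non-physical fits) and defined as 0 for
  the zero tensor. The clipping applies to FA only: the ALPS index reads
  raw axis diffusivities Dxx/Dyy/Dzz, not eigenvalues, so the fitted
  components are preserved untouched.
- A brain mask is optional; by default all voxels with usable signal are
  fitted.

## The ALPS index

`compute_alps` implements

ALPS = mean(Dxx_proj, Dxx_assoc) / mean(Dyy_proj, Dzz_assoc)

where each of the four terms is the mean of one tensor diagonal element
over one ROI. Numerator and denominator are means of the two ROI-level
means — equal ROI weighting — not pooled voxel means. The equation is
written over four named ROI quantities, and equal weighting keeps the
index independent of the relative sizes of the two ROIs (verified by a
test that shrinks one ROI of a homogeneous phantom).

ROI selection (`select_alps_rois`) takes an integer atlas label volume
(ICBM-DTI-81-style) and applies, in order: label membership (projection =
superior + posterior corona radiata treated as one union ROI; association
= superior longitudinal fasciculus), a strict FA > 0.2 mask (a voxel at
exactly 0.2 is excluded) to keep CSF out, an optional half-open band of
left–right voxel indices (the "x-range" through which the medullary veins
pass), and a hemisphere filter. The hemisphere defaults to the left,
where the index's vein geometry is defined; the world x coordinate from
the affine decides the side. ROIs smaller than `min_voxels` (default 5)
are rejected rather than silently averaged.

Axis convention: all volumes must be RAS-oriented and axis-aligned so
that the first voxel axis is left–right and Dxx genuinely means
left–right diffusivity. Orientation is validated from the NIfTI affine;
file loaders reorient to canonical RAS first. The default x-range is
`None` (no restriction) because atlas-specific vein bands are a property
of the atlas in use; the configured value, like every other ROI setting,
is recorded in a provenance hash/sidecar so a reported index can always
be traced to its selection rules.

## The phantom generator

`make_tensor_phantom` builds two axis-aligned fiber boxes in the left
hemisphere of a 40×40×20-voxel, 2 mm isotropic RAS grid (the voxel size
matching common clinical resampling): a projection-like population with
principal axis along z, diag(d_perp + d_x_boost, d_perp, d_parallel), and
an association-like population along y, diag(d_perp + d_x_boost,
d_parallel, d_perp), in an isotropic background. The additive x-axis term
`d_x_boost` stands in for perivascular water movement, so the analytic
index is (d_perp + d_x_boost)/d_perp exactly, independent of overall
scale. Defaults (d_parallel 1.2e-3, d_perp 0.5e-3, d_x_boost 0.12e-3,
background 0.8e-3 mm²/s) give fiber FA ≈ 0.45 and ground-truth ALPS 1.24
— a typical healthy-older-adult value.

`simulate_dwi` adds Rician noise (magnitude of a complex Gaussian), the
correct model for magnitude MR data; at low SNR this inflates the mean
signal, which the simulation reproduces and a test asserts. `sigma = 0`
returns the exact model signal, which makes the noiseless
simulate → fit → index round trip an exact self-consistency oracle
(recovered to ≤ 1e-9 in tests).

What the phantom does **not** emulate: oblique or crossing fibers (both
populations are axis-aligned so the analytic truth stays exact), partial
volume, susceptibility/eddy artifacts, motion, or realistic anatomy.
Passing phantom tests therefore demonstrates correctness of the
estimator chain, not robustness to acquisition artifacts — those are
assumed to be handled upstream, since the package consumes preprocessed,
atlas-space data.

## The cohort generator

`make_cohort` draws from a Gaussian copula: one latent standard normal
per variable, a target latent correlation matrix, continuous marginals by
affine transform, binaries by thresholding at the prevalence quantile.
The matrix is validated (symmetry, unit diagonal, positive
semi-definiteness — violations report the offending eigenvalue) and
factorized by eigendecomposition so semidefinite targets are accepted.

Group effects are specified as |SMD| plus a direction flag (the
published screen reports one group effect with inconsistent sign between
summary and results sections, so the generator never guesses signs from
magnitudes). A requested SMD is converted into the latent correlation
between the binary's latent and the outcome that yields exactly that
expected Cohen's d after thresholding, via truncated-normal moments and
a Brent solve. This was chosen over post-hoc mean shifting: shifting the
outcome after the draw distorts its marginal and attenuates every other
correlation target when several binaries target the same outcome (with
the five group effects used here the attenuation reaches ~12%), whereas
the latent-loading construction keeps the copula exact — marginals
untouched, all correlation and SMD targets holding simultaneously in
expectation. A test verifies both the round trip of the inversion and the
preservation of the outcome marginal.

`published_screen_spec` encodes the study conditions this package
models: 71 subjects, ALPS ~ N(1.24, 0.10), female prevalence 44/71, and
the published effect set (age r = −0.434, waist r = −0.455, GFAP
r = −0.201, female-sex SMD +1.0769, diabetes −0.7662, etc.). Because a
correlation matrix with ~20 variables all correlated with ALPS but
mutually uncorrelated is not positive semi-definite, the preset uses a
single-factor structure: every variable loads on the ALPS latent with its
published r, giving corr(i, j) = rᵢ·rⱼ between covariates. That is always
PSD, reproduces every published ALPS association exactly in expectation,
and is epidemiologically reasonable (age, waist, BMI and lipids are in
fact mutually correlated). Marginal means/SDs for covariates are
plausible clinical values for community-dwelling older adults; the
screen's statistics are location/scale-free, so only the correlations
matter downstream.

What the cohort generator does not emulate: non-Gaussian marginals
(skewed labs such as triglycerides), variable-specific missingness
(several published (r, p) pairs imply effective n < 71; the screen
handles missingness by pairwise deletion and always reports effective n,
but the generator produces complete tables), and any causal structure
beyond the single factor.

## The association screen

- Pearson tests use the exact t transform t = r·√(n−2)/√(1−r²) on n−2
  df. One-tailed tests require a pre-declared direction; when the sample
  sign contradicts it, p is the declared tail's probability (> 0.5),
  never silently flipped. The one pre-declared one-tailed test in the
  bundled battery is blood GFAP against ALPS (astrocytic injury assumed
  to impair glymphatic transport, hence negative).
- Group comparisons use the pooled-variance Student t-test (Welch by
  flag) and SMD = Cohen's d with pooled SD (Hedges' g by flag), signed
  condition-present minus condition-absent.
- FDR control is Benjamini–Hochberg step-up at q = 0.05 by default,
  applied once across the full declared family (continuous and binary
  batteries together). Adjustment is delegated to statsmodels and
  cross-checked in tests against a definition-based brute-force step-up.
- Normality of the outcome is checked first with a Lilliefors-type test:
  the KS distance to the normal with sample-estimated mean/SD, with a
  seeded Monte-Carlo null (default 2000 simulations) for the p-value, and
  the reported p capped at 0.200 — the upper bound the classical lookup
  tables (and common statistical packages) report. The raw Monte-Carlo
  estimate is kept alongside. Note the cap engages with probability ~0.8
  under the null (the p-value is uniform), and the test's power against a
  uniform alternative at n ≈ 70 is moderate (~0.5); the tests assert
  these calibrated rates.
- p-values are reported in tables to full precision; displays round to 3
  decimals.

## Clinical classifications

Metabolic syndrome is ≥ 3 positive of 5 criteria — waist ≥ 90 cm male /
≥ 80 cm female; SBP ≥ 130 or DBP ≥ 85 mmHg; fasting glucose ≥ 100 mg/dL;
HDL < 40 male / < 50 female mg/dL; TG ≥ 150 mg/dL — with every boundary
exactly as written (≥ vs. <). CKD is eGFR < 60 or proteinuria (urine
protein ≥ 1+, ACR ≥ 30, or PCR ≥ 150); the eGFR equation itself is not
recomputed — eGFR is consumed as a given column. Overweight is BMI ≥ 25
with BMI = weight/height². The estimated anion gap is Na − (Cl + HCO₃),
the simplest convention consistent with "estimated"; this is an assumption
and is documented as such.

Missing-data semantics are explicit three-valued logic: a classification
returns True only when forced true, False only when the available
evidence decides it, and None (→ pandas NA in tables, treated as missing
by the stats layer) when missing inputs could flip the outcome. Derived
ratios with missing inputs are NaN, never 0.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately modest
sizes chosen to exercise every code path with tight tolerances: phantoms
of 32 000 voxels × 33 volumes, noisy-fit checks on 1000 voxels × 32
directions, 300–1000 seeded cohort replicates of 71 subjects for
calibration/power properties, and 200–2000 Monte-Carlo draws for
normality p-values. All randomness flows through
`numpy.random.default_rng` seeds; batch runs, screens and the CLI write
their seeds and configuration hashes to manifests so every output is
regenerable bit-identically.

## Known limitations

- Axis-aligned phantoms only; no oblique-fiber ground truth.
- The ALPS implementation is single-hemisphere (left by default);
  bilateral or regional variants are not provided.
- Registration to atlas space is out of scope: inputs are assumed already
  deformably normalized, and the x-range/label defaults must be chosen
  for the atlas actually in use.
- The Lilliefors Monte-Carlo p is exact only up to simulation error
  (~1/√n_sim); increase `n_sim` for publication-grade reporting.
- The cohort generator's effect preset reproduces pairwise targets in
  expectation at any n, but a single 71-subject draw scatters widely
  (sampling SD of r at n = 71 is ≈ 0.1); replicate-averaged checks are
  the intended use.
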