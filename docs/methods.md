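# Methods

## The kinetic model

Tissue contrast-agent concentration is approximated by relative signal
enhancement `E(t) = (S(t) − S₀)/S₀`, with `S₀` the per-voxel mean of the
pre-contrast frames. This assumes signal is linear in concentration over
the working range, with one proportionality constant shared by blood and
tissue; the constant therefore cancels from the model fit (tested as scale
invariance), and all parameters are *blood-referenced* — no hematocrit
correction is applied, so ECV values are relative to whole-blood rather
than plasma concentration.

The tissue curve follows the single-compartment Kety/Tofts-type form

    Ct(t) = Ktrans · ∫₀ᵗ Ca(τ) · exp(−kep · (t − τ)) dτ,
    kep   = Ktrans / (ECV/100),

with `Ktrans` in min⁻¹ (converted internally to s⁻¹ against second-valued
time grids), `ECV` in mL per 100 mL of tissue, and the derived mean transit
time `MTT = (ECV/100)/Ktrans` reported in seconds. The model has no plasma
volume term and no fitted bolus-arrival delay: injection is at t = 0 and
phantoms honour the same convention, so simulated and fitted curves share
one clock.

### Numerical evaluation of the convolution

The convolution is computed by the standard exponential-convolution
recursion: on each frame interval the AIF is taken as linear between its
samples and the integral against the exponential kernel is evaluated in
closed form, with a series fallback for `kep·Δt < 10⁻⁶` and a first-order
IIR filter (scipy `lfilter`) fast path on uniform grids. The scheme is
exact for piecewise-linear inputs, so the only discretization error is the
linear interpolation of the AIF between frames; the test suite checks
agreement with direct trapezoid quadrature on a 10×-refined grid to within
0.5% over `Ktrans ∈ [0.1, 1.5]`, `ECV ∈ [10, 60]`.

### Fitting

Per-lesion ROI-mean curves (not voxelwise maps) are fitted — this matches
per-tumour parameter reporting, averages noise down before the nonlinear
step, and keeps runtime trivial. The optimizer is scipy's bounded
trust-region least squares with start `(Ktrans, ECV) = (0.3, 30)`, bounds
`Ktrans ∈ [10⁻⁶, 10] min⁻¹`, `ECV ∈ [10⁻³, 100]`, and three additional
starts if the first does not converge. Because the objective is flat in
the near-zero-uptake valley (any small `Ktrans` with small `ECV` predicts
a near-zero curve), the boundary null model `(10⁻⁶, 1.0)` is evaluated
explicitly and returned when it fits at least as well — this is what
drives an all-zero observed curve to `Ktrans ≤ 10⁻⁶`. Non-convergence
returns the best parameters seen with `converged = False`, never an
exception. The suite verifies the fitted objective is never worse than the
best point of a 200 × 200 grid over the parameter box.

## AIF extraction

The operator's coarse aorta ROI is refined by keeping the voxels whose
peak enhancement (maximum over dynamic frames only; pre-contrast
enhancement is ≈ 0 by construction) reaches the 95th percentile of peaks
within the ROI. The percentile uses linear interpolation between order
statistics and the threshold is applied as ≥ — stated explicitly because
different estimators move the cut between order statistics (on peaks
1…100 the threshold is 95.05 and exactly 5 voxels survive). The AIF is the
frame-wise mean over retained voxels. Voxels with `S₀ ≤ 0` cannot be
normalised; they are flagged and excluded with a logged count.

## Perfused-tumour segmentation

A per-voxel maximum-enhancement map (dynamic frames only) is thresholded
at `fraction ×` the maximum *within the candidate ROI* — the per-lesion
reference makes the cut adapt to each lesion's enhancement level, which a
global-image reference would not. The default `fraction = 0.5` is an
implementation choice (the threshold percentage used in the motivating
analysis is not public) and is recorded in every output; absolute volumes
therefore depend on it, while the procedure, its monotonicity (larger
fractions never grow the ROI) and the subset property do not. Perfused
volume is `voxel count × voxel volume / 1000` cm³ with the default voxel
volume 48.8 mm³.

## Longitudinal analysis

For multi-lesion patients only the index lesion — largest baseline
*perfused volume*, ties broken to the lowest lesion id — enters the
response analysis, as the lesion least affected by partial-volume effects.
(Volume, not anatomical diameter, defines "largest": the analysis is
volume-centric throughout.) Four parameters (volume, Ktrans, ECV, MTT) ×
three intervals (baseline→4w, 4w→10w, baseline→10w) give 12 change records
per patient, each with absolute and percentage change; a missing timepoint
produces explicit flagged rows, and a zero earlier value makes the percent
change *undefined* rather than ±∞.

## Statistics

- **Normality gate:** one-sample Kolmogorov–Smirnov against a normal with
  the sample's own mean and SD, α = 0.05. With estimated parameters the
  classical KS test is conservative (the Lilliefors correction is not
  applied). Groups with n < 5 are never certified normal — the gate has
  essentially no power there — and route nonparametric; zero-variance
  samples likewise.
- **Group comparison:** both groups normal → Welch (unequal-variance)
  independent t-test; otherwise Mann–Whitney U, exact for combined n ≤ 12
  without ties, normal approximation with tie correction otherwise. Two
  sided, α = 0.05, no multiple-testing correction (none is applied in the
  study design this mirrors).
- **Paired tests:** two-tailed paired t across visit pairs.
- **ROC/AUC:** computed only for parameter changes whose group test passes
  α. The AUC is directional (higher score = predicted progressor;
  negating scores maps AUC → 1 − AUC) with the orientation recorded.
- **ICC:** two-way random-effects, absolute-agreement, single-measure
  ICC(2,1) — the standard choice for two fixed readers measuring the same
  lesions — with 95% CI, computed via pingouin and cross-checked against
  the ANOVA mean-squares closed form in the tests. Verbal grading uses
  half-open bands `[0.81, 1]` excellent, `[0.61, 0.81)` good, `[0.41,
  0.61)` moderate, `[0.21, 0.41)` fair, below poor; the bands are
  exhaustive over [−1, 1] (the conventional published bands leave gaps at
  0.80–0.81 and 0.20–0.21, closed here by the half-open convention).

## The synthetic phantom and cohort

The phantom emulates an abdominal DCE protocol: 6 pre-contrast frames at
2 s intervals preceding injection at t = 0, 120 dynamic frames at 2.4 s
intervals, voxel volume 48.8 mm³. The AIF is a population bolus — a
gamma-variate first pass (default peak enhancement 4.0 at 18 s
post-injection, arrival 10 s) plus a recirculation/equilibrium tail —
zero before arrival and non-negative; any smooth realistic form would do,
since real analyses measure the AIF per patient. Aorta voxels carry the
AIF, spherical lesion voxels carry their `tissue_curve`, optionally with a
1-voxel rim at reduced amplitude to emulate partial-volume periphery, and
the signal model is `S = S₀(1 + E) + N(0, (noise_sd·S₀)²)` — additive
Gaussian on *signal*, matching MRI magnitude noise at high SNR while
staying simple. No motion, coil bias or T1/relaxometry effects are
simulated, so passing tests demonstrate correctness of the estimation
chain, not robustness to scanner physics; registration-free analysis is
mirrored by motion-free phantoms.

The cohort generator emulates the study design the package targets: 14
patients of whom 3 progress at 6 months, 1–5 lesions each, three visits.
Baseline Ktrans is lognormal with mean 0.96 and SD 0.63 min⁻¹ (matching
the baseline summary statistics of the motivating cohort), ECV uniform on
[20, 60] mL/100 mL. Every lesion's Ktrans falls by week 4 (patient-level
factor U(0.25, 0.55), consistent with the ~0.96 → 0.37 group mean);
between weeks 4 and 10 progressors' lesions rise by the configured effect
(default doubling) while non-progressors' stay flat or fall (factor
U(0.7, 1.0)). Volumes fall by week 4 (factor U(0.3, 0.75), median ≈ −48%)
and follow the same group split afterwards. Inter-lesion heterogeneity
within a patient is real but of unpublished magnitude, so it is an
explicit parameter (relative SD of the per-lesion response depth, default
0.25) rather than a claimed value; it scales the depth of each lesion's
week-4 fall without ever violating the group-direction contract, so
noiseless truth always rank-separates the groups.

## Problem sizes and defaults in the checks

The acceptance script fits 100 simulated lesions with
`Ktrans ~ U(0.1, 1.5) min⁻¹`, `ECV ~ U(10, 60)` on the full 126-frame
protocol, with 2% signal noise averaged over a 25-voxel ROI; the
end-to-end determinism check uses a rendered 4-patient / 2-progressor
cohort with a shortened (60-frame) dynamic series, a size chosen because
determinism is independent of grid and cohort size. Effect detection uses
the full 14-patient / 3-progressor design on noiseless truth.

## Known limitations

- Signal-to-concentration linearity ignores T1 saturation; at a standard
  dose the aortic peak is the most affected, biasing Ktrans upward in real
  data. Parameters are comparable within-protocol, not absolute.
- No plasma-volume term: highly vascular lesions fold blood signal into
  Ktrans/ECV.
- No fitted bolus-arrival delay; a real lesion–aorta transit offset of a
  few seconds biases fits slightly.
- The perfused-volume threshold fraction is a free parameter; absolute
  volumes are threshold-dependent.
- ROC areas are reported without confidence intervals, and no
  multiple-testing correction is applied across the 24 parameter/interval
  comparisons.
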