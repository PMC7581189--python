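# Methods

This note documents the models and procedures the package implements,
the choices made where the design was open, and what the synthetic
generator does and does not emulate.

## Task geometry and stimulus design

Objects sit on circles centred on the avatar's nasion, at array angles
120°, 150°, 210° and 240° measured **clockwise from the upward
vertical** (the zero reference is a package convention; it places
120°/150° in the observer's lower-right hemifield and 210°/240° in the
lower-left, and is configurable). The anterior distance of each circle
follows from a right triangle at the nasion with fixed tan α = 0.268:
`distance = round(radius × tan α)`, rounded half away from zero to
integer virtual mm. This reproduces five of the six tabulated
radius/distance pairs exactly (335→90, 480→129, 380→102, 510→137,
590→158); the tabulated 580→151 disagrees with the formula value 155.
The package computes the formula value by default and ships the
tabulated values as an explicit override (`use_printed_distances=True`)
rather than deciding which is authoritative.

Each array holds two hands and one house or one hand and two houses,
with exactly three hands and three houses per hemifield. Crossing
target category (2) × instruction condition (3) × target position (12)
under these constraints yields 72 stimulus sets. A session shows each
set twice and draws 36 residual trials by seeded rejection sampling so
that category (90/90), condition (60/60/60) and position (15 each)
marginals stay balanced; trials are arranged into 6 blocks of 30 with
exactly 10 per condition per block. Virtual mm map to screen degrees
through a configurable scale (default 0.02°/virtual mm), a perspective
stand-in for the unspecified screen projection.

## Synthetic BOLD generator

Trials last 20 s: 5 s baseline fixation, cue (gaze shift + spoken word)
at 5 s, go at 10 s, ~2 s response, blank to 20 s. Runs hold 30 trials
at TR = 1.5 s plus 12 s of trailing rest so the last trial's analysis
epoch stays inside the run. The default grid is 24³ voxels at 3 mm
(desk-scale, configurable) with an ellipsoidal "brain" of baseline 100;
analyses in the test suite use 14³ for speed, stated per test.

Three spherical areas (5 mm radius, ≥ 4 voxels apart) carry
condition-dependent responses built from three event kinds convolved
with the canonical double-gamma HRF (peak 6 s, undershoot 16 s,
undershoot ratio 6, 32 s support, peak-normalized):

| area        | cue impulse | go impulse                    | cue→go boxcar      |
|-------------|-------------|-------------------------------|--------------------|
| gfp-like    | 1.2% all    | 1.2% all                      | —                  |
| hlip-like   | 1.2% all    | 1.2 / 1.5 / 2.0% (U / AI / AU)| —                  |
| ifj-like    | —           | —                             | 1.2% AI and AU only|

Amplitudes are free parameters (the emulated study reports none in %
signal change); the defaults are conventional event-related effect
sizes chosen once for test power against the default noise, and the
ambiguity ordering encodes the qualitative findings being emulated.
Noise is stationary AR(1) (ρ = 0.3, marginal SD 0.8% of baseline) plus
per-voxel cosine drifts with periods 128–300 s. Subjects get additive
random intercepts (SD 0.2%) on their nonzero amplitudes, which is what
the hierarchical model's varying intercept absorbs. "SNR ≥ 5" in
recovery tests means peak amplitude ≥ 5 × the white-noise SD
(amplitudes 1.2–2.0% over SD 0.24%).

Eye traces are sampled at 50 Hz (scanner-session rate): fixation at the
origin, a 100 ms minimum-jerk saccade starting 200 ms after the go,
Gaussian position noise, and optional blink artifacts (brief 40°
excursions exceeding the 1000°/s cleaning threshold). The landing
object is the true target with the condition's probability from the
choice model (default 0.94, 0.94/2, 0.94/3) and otherwise uniform among
the other objects of the gazed-at array, so planted hit rates equal the
guessing-model expectations exactly.

What the generator does **not** emulate: scanner physics (slice timing,
field inhomogeneity, multiband artifacts), physiological noise,
realistic cortical geometry or between-area correlation, spatial noise
correlation, head-motion-coupled signal, or tracker-specific eye-signal
artifacts beyond blinks. Passing tests therefore certify the analysis
machinery and its statistical calibration on data satisfying the
models' assumptions, not performance on real acquisitions.

## GLM

Designs hold one HRF-convolved regressor per modelled event type ×
condition (impulse duration by default; the spoken-cue duration is
configurable), six motion regressors, discrete-cosine drift columns and
a constant. The drift count is `floor(2 · T · cutoff)` for cutoff
1/128 Hz — drift handling lives in the design rather than as a
pre-filter, the standard statistical-parametric equivalence. Estimation
is voxelwise OLS (exact on noiseless runs); autocorrelation is not
modelled by default (an AR(1) prewhitening flag would change variances,
not effects, and the emulated analysis describes none). Contrast t maps
use the OLS standard error with df = T − rank(X). Runs combine by fixed
effects (mean effect, pooled variance). The second level is a voxelwise
one-sample t test; zero-variance voxels are flagged degenerate, not
dropped. Clusters are face-connected (6-neighbour, 18/26 configurable)
supra-threshold components with a minimum extent (default 6 voxels).
Smoothing uses σ = FWHM / (2√(2 ln 2)) per axis in mm.

## ROI localization

Individual ROIs are the supra-threshold voxel with the maximum contrast
statistic among significant clusters (voxel p < 0.05 uncorrected,
extent ≥ 6 — the uncorrected reading is deliberate, matching the group
thresholds), tie-broken by distance to the literature seed and then by
lowest linear index (the tie-break chain is fixed because none is
specified anywhere). The 10 mm seed-proximity criterion applies to the
GFP localizer by default (low contrast SNR) and can be enabled for any
ROI. Localized subjects get 5 mm spheres at their peak; others fall
back to 10 mm spheres at the group seed. Sphere membership is the
closed ball over voxel centers — note that on a 3 mm grid a 5 mm ball
holds 19 voxels (center, 6 face neighbours at 3 mm, 12 edge neighbours
at 4.24 mm).

## Time courses and permutation statistics

ROI series are per-volume means over sphere voxels. Each trial is cut
into a cue-locked epoch (−5 s … +15 s, TR bins; the window end follows
the 20 s trial span) and converted to % signal change against the mean
of the samples acquired in the 5 s before the cue. Condition
trajectories average within subjects first; the SEM is across subjects.

The permutation test pools the two conditions' exchangeable units
(subject-mean trajectories by default, trials optionally), draws random
splits preserving group sizes, and computes per post-cue bin the
two-sided p of the observed difference of means. The default estimator
is the validity-preserving (1 + #{|Δ*| ≥ |Δ|}) / (n + 1); the plain
fraction is exposed but can be exactly zero. Pooled rows are put in a
canonical sort order before splitting so equal-size groups give
identical p values when swapped and results are bit-reproducible per
seed. The FDR family is the post-cue bins of one ROI × one condition
pair (configurable); Benjamini–Hochberg q < 0.05 flags significance.
Under a simulated global null the mean flagged-bin proportion measures
≈ 0.01–0.02, under the nominal 0.05.

## Hierarchical credible-band model

Per condition and ROI, epochs are modelled as
`y = X(t) w + b_subject + ε` with X the 7-column Fourier set on the
epoch window T: constant plus sin/cos at periods T, T/2, T/3 (the
deconvolution-package convention; the source analysis names only "7
sinusoidal basis functions"). Priors are weakly informative:
w ~ N(0, 10²) in % signal units, half-normal(5) on the noise and
intercept scales. The varying intercept is per participant within each
condition's separate model.

The sampler is a blocked Gibbs scheme: conjugate multivariate-normal
updates for w, conjugate normal updates for the intercepts, and
univariate slice sampling (stepping-out/shrinkage) in log-scale for σ
and τ under their half-normal priors. Every update is an exact
conditional draw, so there are no divergences to report; convergence is
monitored with split-R-hat and ESS (arviz), and R-hat > 1.05 on any
group weight attaches an explicit warning to the fit. Defaults are 4
chains × 1000 draws after 500 warmup; calibration experiments use 2 ×
500 after 300, which the R-hat check accepts. Credible bands are
pointwise 2.5/97.5 percentiles of the group-trajectory draws (X w;
intercepts average out at the group level); a band-overlap utility
reports per-bin overlap between conditions. On 100 cohorts simulated
from the model (15 subjects, 4 epochs each) the 95% bands cover the
generating trajectory at ~96% of (replication, bin) pairs.

## Searchlight decoding

Inputs are run-wise cue-locked condition coefficients from per-run
GLMs (go events pooled across conditions within these designs, so
go-locked condition differences also reach the cue coefficients), which
keeps leave-one-run-out folds independent. Per sphere center (default
radius 9 mm = 3 voxels; the radius is unrecoverable from the source and
visibly affects hotspot extent, so it is a prominent parameter), a
linear SVM (C = 1) is trained with features z-scored on the training
folds only; per-voxel accuracy minus 0.5 forms one map per subject.
Group inference smooths the maps (4 mm FWHM) into a one-sample t map
thresholded at p ≤ 0.001 — reproduced as specified although accuracies
are not normal — and the rank-based complement tests per-ROI mean
accuracies against chance with a two-sided Wilcoxon signed-rank test
(zero differences dropped, so an exactly-at-chance subject leaves the
p value unchanged).

## Eye movements and behavior

Cleaning removes samples whose finite-difference speed exceeds 1000°/s
(with one padding sample each side). Division by the temporal mean is
implemented for raw positive tracker units and errors on zero-mean
channels; the synthetic chain runs on calibrated degree traces where
that step is skipped. The response saccade is the velocity peak in
[go − 500 ms, go + 1800 ms]; fixations are 200 ms means before and
after the peak with an 80 ms guard that keeps in-flight samples out
(slot spacing on an array can be as small as 1.6°, so in-flight
contamination would otherwise misassign landings). The manual validity
check of the emulated study is replaced by a deterministic margin rule:
valid iff the nearest object lies within 2° and the second-nearest is
at least 1° farther; both thresholds are configurable. Hit-rate
summaries weight subjects by valid-trial counts (frequency-weight SD,
denominator Σw − 1) and compare per-subject rates against the guessing
model (reference × 1, ½, ⅓) with two-sided one-sample t tests; with
truth at the expectations the tests reject at ~5%.

## Problem sizes and runtime

Validation experiments run at desk scale by the package's own choice:
500 null datasets × 2,000 permutations for FDR calibration, 100
model-simulated cohorts of 15 subjects (2 × 500 draws) for band
coverage, a 10-subject cohort on a 14³ grid for chance-level decoding,
and an 8-subject high-SNR cohort for recovery properties. The full
`scripts/acceptance.py` run takes a few minutes on one CPU; the
generator and every analysis accept larger grids, cohorts, permutation
counts and draw budgets through their parameters.

## Known limitations

* OLS without autocorrelation modelling understates first-level
  variances under AR(1) noise; inference in the pipeline relies on
  permutation, rank and hierarchical methods where this matters.
* The fixed-effects run combination ignores between-run variance.
* The hierarchical model treats epochs as exchangeable within subject
  and does not deconvolve overlapping events; epochs are modelled
  directly, as the emulated analysis does.
* The choice model makes trials independent; sequential effects,
  learning and fatigue are absent.
* Group analyses assume a shared grid (the generator's); no spatial
  normalization is implemented, which is out of scope.
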