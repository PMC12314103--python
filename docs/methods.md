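# Methods

This note documents the models, conventions and numerical choices behind
`microskill`, and what the synthetic-data tests do and do not demonstrate
about real surgical video.

## Setting and conventions

The unit of analysis is a *trial*: one interrupted suture in an
end-to-side microvascular anastomosis exercise, annotated with four
phases — A (grasp and insert the needle), B (push and extract it),
C (pull the threads to the first knot), D (tie three knots and cut).
Inputs are per-frame outputs of two perception models: a vessel
segmentation (reduced to a pixel-count series VA(t)) and an
instrument-tip detector (per-hand x, y and a validity flag that drops
whenever the tool leaves the microscope's field of view).

Fixed conventions: pixel coordinates with origin top-left; 0-based frame
indices; half-open phase intervals [start, end); time derived from a
caller-supplied frame rate (default 30 fps — recording rates vary by
setup and all outputs simply scale with the supplied value). Each
surgeon's representative value of any parameter is the arithmetic mean of
their first two trials, which bounds learning effects from repetition.

## Vessel-deformation parameters

From VA(t) we compute:

* **CV-VA** = σ/μ with the sample (n−1) standard deviation.
* **ΔVA**: VA is first divided by its within-window mean, then forward
  differences are scaled by the frame rate, giving a dimensionless rate
  (units 1/s). Normalizing by the mean makes ΔVA invariant to absolute
  vessel size, magnification and image resolution; it is what puts the
  default deformation threshold on an order-1 scale. Alternative
  normalizations (first frame, none) are available via
  `va.normalization`. VA is not pre-smoothed: a segmentation area is
  already an integral over thousands of pixels, and a single forward
  difference is the most transparent estimator of dVA/dt.
* **Max-ΔVA**: the largest |ΔVA| in the analysed window.
* **No. of TDE** (tissue-deformation errors): excursions of |ΔVA| beyond
  a threshold (default 1.13, from a mean ± 1.96 SD band of ΔVA pooled
  over a reference training cohort; `cohort_tde_threshold` recomputes the
  band — returning its larger absolute edge — for any new cohort, and the
  Monte-Carlo tests confirm the 1.96 SD rule on a standard-normal pool).
  By default each maximal above-threshold run of common sign counts once
  (`excursion` mode): the quantity reads as a count of error *events*.
  A `per_sample` mode (every above-threshold frame pair counts) is kept
  as configuration; excursion counts are never larger. Samples exactly at
  the threshold do not trigger — the boundary is not an error.

## Instrument kinematics

Tracks are partitioned into maximal contiguous valid runs. Within each
run, positions are smoothed by Savitzky–Golay local quadratic regression
(window 7 frames at 30 fps by default; window 1 disables smoothing and is
used in every closed-form test). Smoothing is deliberately conservative:
NJI requires a third derivative, which amplifies detection jitter
roughly as (fps)³. First, second and third derivatives are taken by
central differences within runs, one-sided at run ends; derivatives never
span a gap, because bridging an unobserved interval would fabricate
motion.

* **Path distance** (PD): the sum of Euclidean steps between consecutive
  within-run positions. Gaps contribute zero. PD is additive and at least
  the chord of any single run.
* **Normalized jerk index** (NJI): ½ · t⁵/D² · ∫‖da/dt‖² dt, with the
  squared Euclidean norm of the 2-D jerk vector, the integral accumulated
  by the trapezoid rule within runs, t the summed duration of valid runs,
  and D the path distance. The t⁵/D² normalization makes the index
  dimensionless and invariant to temporal and spatial rescaling and to
  rigid motions of the trajectory. A single ideal minimum-jerk reach —
  displacement profile d·(10τ³ − 15τ⁴ + 6τ⁵), whose squared-jerk integral
  is 720·d²/t⁵ — scores exactly 360; the sampled implementation is within
  1% of that at 1000 frames and converges with sampling rate. A
  stationary tip (D = 0) is a degenerate input, not a zero.

## Phase stratification

The phase window is sliced out *before* any metric is computed, so
per-phase NJI uses phase-local t and D. Whole-trial ("All") motion
metrics are assembled from the per-phase kinematics as separate segments:
derivatives never span a phase join, no inter-phase step is counted, and
PD over phases is exactly additive (A+B+C+D = All). Whole-trial vessel
metrics use the union window directly, so a deformation event spanning a
join is still one event. Cells that cannot be computed in a window (for
example a hand never detected during a phase) are missing, not zero, and
downstream statistics drop them pairwise.

## Rubric scoring and reliability

Nine technical categories (instrument handling, respect for tissue,
efficiency, suture handling, suturing technique, quality of knot, final
product, operation flow, overall performance), each scored 1–5 by three
blinded raters. A surgeon's category score is the mean over raters and
the first two trials; the total (9–45) labels the surgeon good when
≥ 35, poor otherwise. The boundary is assigned to *good*; cohort totals
are empirically bimodal around 35, so the choice is inert on study-like
data but fixed for determinism. Interrater reliability is Cronbach's α
with raters as items, computed per category across surgeons'
trial-averaged scores (a whole-scale α over rater totals is also
reported); α is 1 for identical raters, ≈ 0 for independent noise, and
invariant to per-rater offsets.

## Screening and feature selection

Every (parameter, phase) cell is correlated with every rubric category by
Spearman's ρ (mid-rank ties, ρ = Pearson correlation of ranks), two-sided
p by the t approximation by default or by the permutation distribution
(exhaustive below 50 000 permutations, Monte Carlo with an add-one
correction above); at cohort sizes near n = 14 the permutation method is
preferable and is what the oracle tests exercise. No multiple-testing
correction is applied — the screen is descriptive, mirroring common
practice in small skill-assessment cohorts — though the `significant`
flag is simply p < α with α = 0.05.

Feature selection is per model family: Model 1 draws from the vessel
parameters (CV-VA, Max-ΔVA, TDE count), Model 2 from the motion
parameters (PD and NJI per hand), Model 3 is their union. Each parameter
with at least one significant cell contributes its single best phase
cell — most significant categories, ties broken by smaller median p
across the nine categories, then by a fixed phase order (All, A, B, C,
D). The rule is deterministic by construction and, on the reference
screening table of an expert-rated 14-surgeon cohort (shipped with the
test suite), selects exactly TDE-count/phase C and Max-ΔVA/phase B for
the vessel model and right-PD/All, left-PD/All, left-NJI/All and
right-NJI/phase C for the motion model.

## Discriminant analysis and ROC

Fisher's linear discriminant with pooled within-class covariance (n−2
denominator) and equal priors: w = S⁻¹(μ_good − μ_poor), intercept at the
midpoint of the class means. Priors shift only the decision threshold,
and the ROC is threshold-free, so the prior choice cannot affect any
reported number. A singular covariance (e.g. duplicated features) gets a
small ridge, 10⁻⁸·trace/dim, and the event is logged. AUC is computed by
the rank (Mann–Whitney) formulation with half-credit for ties, which the
tests verify equals both the exhaustive pairwise statistic and the
trapezoidal area under the empirical curve; 95% confidence intervals use
a stratified bootstrap percentile (2000 resamples by default, resampling
the good and poor groups separately — assumption-light at n = 14).

## Synthetic cohorts

The generator encodes the causal structure the analysis assumes: a latent
per-surgeon skill in [0, 1] degrades every channel linearly via
(1 − skill).

* **Motion**: each phase is a chain of minimum-jerk submovements between
  waypoints (wider-ranging for the dominant right hand). Low skill adds
  Poisson(3·(1−skill)) detour submovements per phase (inflating PD) and
  white jerk-level noise (150·(1−skill) px/s³) triple-integrated into a
  position perturbation and sin²-tapered to vanish at submovement
  boundaries — raising NJI without tearing the path.
* **Vessel area**: baseline 5000 px with slow sinusoidal drift (1.5%)
  and frame noise (0.2%), plus Poisson(4·(1−skill)) deformation events
  per trial: a fast half-second cosine ramp of 40% relative amplitude
  (peak |ΔVA| ≈ 1.26, clearing the 1.13 threshold with margin above the
  noise floor) followed by a slow 5-second sub-threshold recovery, so one
  injected event is exactly one counted excursion. Events are placed
  preferentially in phases B and C, where needle extraction and thread
  pulling stress the vessel wall.
* **Rubric**: category latent 1 + 4·skill + N(0, 0.4) per rater, trial
  and category, rounded and clipped to [1, 5].
* **Cohort**: 14 surgeons, two trials, three raters; skills bimodal
  (half from 0.80 ± 0.06, half from 0.25 ± 0.08), yielding totals on
  both sides of the 35-point cutoff. Phase durations average 15/10/15/25
  s — a roughly one-minute trial, long enough for phase-local statistics
  while keeping the full test suite and the acceptance run in seconds.
  One root seed spawns an independent substream per surgeon, so output is
  byte-identical for a fixed seed and surgeons are statistically
  independent.

What the synthetic tests show: that the pipeline recovers a known skill
structure end-to-end (ground-truth cluster separation with AUC ≥ 0.9
under the default settings) and that every primitive matches its
closed-form or brute-force oracle. What they do not show: robustness to
the failure modes of real perception outputs — segmentation
misclassification under instrument shadows, detector identity swaps,
perspective and depth effects of 2-D imaging — none of which the
generator emulates.

## Known limitations

* All kinematics are 2-D; out-of-plane motion is invisible and depth
  foreshortening biases PD downward.
* The TDE threshold's absolute value is meaningful only under the same
  ΔVA normalization used when the threshold was derived; the default
  within-window mean normalization is an assumption, and new cohorts
  should refresh the threshold with `cohort_tde_threshold`.
* NJI at a phase's scale depends on the smoothing window when tracks are
  noisy; comparisons are only meaningful at fixed preprocessing
  settings.
* The discriminant models are fit and evaluated in-sample on small
  cohorts, as is standard in this literature; the AUCs are descriptive,
  not out-of-sample performance estimates.
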