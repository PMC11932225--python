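# Methods

`bimotap` reimplements, end to end, a screening analysis of bimanual
coordination in aging: participants tap thumb against index finger with
both hands for 15 s, either simultaneously (in-phase) or in alternation
(anti-phase, 180° target relative phase), while a magnetic sensor records
the thumb–index aperture of each hand as a distance waveform in
millimetres.  Nine parameters summarize each trial; group statistics
compare young (18–22 y), young-old (65–74 y) and old-old (≥75 y) adults;
and ROC analysis converts the best-separating parameters into age cutoffs.
Because the original recordings are not public, the package includes a
synthetic-data generator that reproduces the cohort's statistical
structure, so every downstream stage is testable without any download.

## Cohort model and screening

Participants carry age, sex, handedness, MMSE and a pre-screened disorder
flag.  Screening removes, in a fixed order (first matching reason logged):
pre-screened musculoskeletal/CNS/mental disorders, left-handedness, any
trial whose aperture reaches 300 mm (sensor artefact), incomplete
recordings, ages outside every stratum (23–64 are excluded explicitly,
with reason `age_out_of_range`), and MMSE ≤ 23 — the cognitive screen is
applied to the older strata only, so MMSE may be absent for young adults.
Fixing the order makes the exclusion log deterministic and the operation
idempotent; the boundary cases are MMSE 24 (kept) and 299.9 mm (kept).

## Synthetic-data generator

The generator's defaults are the study conditions: per (group, task, hand)
cell it carries the tapping-interval mean/SD, aperture mean/SD and fatigue
slope, and per (group, task) the phase-difference SD, all taken from the
reference cohort's summary table (e.g. young-adult in-phase left interval
0.28 s, aperture 41.07 mm; old-old anti-phase phase SD 40.57°).

* **Contact process.** Right-hand contacts form a renewal process: first
  contact at t = 0, gaps i.i.d. truncated normal (floor 0.05 s, a
  physiological refractory interval).  The distributional form is a
  modelling choice; the reference data report only means and SDs.
* **Phase coupling.** Left-hand contact *k* is the right-hand contact *k*
  plus a normal offset: mean 0 (in-phase) or half the local right-hand
  cycle (anti-phase), SD = phase-SD/360 of the local cycle.  The right
  hand is the reference (all kept participants are right-handed).  A
  consequence worth knowing: left-hand *timing* statistics (count,
  interval mean) are emergent from the right-hand process plus jitter —
  the left column's interval entries parameterize only left-hand
  amplitudes.  Left-hand interval *variability* therefore exceeds the
  right's by construction, matching the observed left-worse-than-right
  pattern.
* **Waveform.** Each open–close cycle is a raised-cosine arch from 0 mm at
  contact to a peak drawn from Normal(amplitude mean + fatigue slope ×
  (t − duration/2), amplitude SD), floored at 1 mm.  Anchoring the linear
  fatigue drift at mid-trial makes the trial-average peak equal the cell's
  amplitude mean while leaving the slope intact; anchoring at t = 0 would
  shift every trial mean by slope × duration/2 (≈ −1 mm), contradicting
  the printed cell means.
* **Heterogeneity and noise.** Each subject draws multiplicative ability
  factors (CV 0.15, clipped to [0.5, 1.5]) on interval and amplitude
  means, shared across all four cells — this produces the within-subject
  correlation a mixed design exploits.  The cell-level SDs in the
  reference table conflate between- and within-subject variance, so the
  split is a free parameter.  Measurement noise is white Normal(0, 0.2 mm),
  clipped at 0; sampling rate defaults to 100 Hz (not stated by the
  device's documentation; configurable).

What the generator does **not** emulate: biomechanics (muscle/joint
dynamics), phase wrapping/slipping under fatigue, non-stationary tap
rates, sensor drift, or any dependence of timing on amplitude.  Passing
tests therefore demonstrate that the analysis chain is correct and well
calibrated under the cohort's reported first- and second-order structure,
not that it has been validated on real recordings.

## Feature extraction

Peaks are local maxima with prominence ≥ 4 mm (10% of the 40 mm target
aperture; plateaus resolve to their first sample); a tap event is the
minimum sample between consecutive peaks.  Contact *times* are refined to
sub-sample precision by intersecting straight-line fits to the two flanks
of √distance around the minimum: the aperture leaves a contact
quadratically, so its square root is locally V-shaped, and the V-fit is
immune to the systematic pull a single parabola suffers when the flanking
arches have unequal curvature (that pull correlates with the phase offset
and would attenuate the measured phase SD by 1–2°).  Contact and peak
*values* stay at the raw samples.

Per hand: total traveling distance (sum of absolute sample-to-sample
changes), mean/sample-SD/OLS-time-slope of the peak apertures (slope 0
means no fatigue), tap count, mean/sample-SD of inter-contact intervals,
and frequency = 1/mean interval (an exact identity).  Per trial: for each
right-hand contact with local cycle c, the left contact nearest the task
target (the contact itself, or a half cycle later) yields an angle
360·lag/c; deviations from the 0°/180° target are wrapped to (−180°, 180°]
and summarized by the circular standard deviation (a `linear` plain-SD
switch exists for sensitivity analysis).  Sample (n−1) SDs are used
throughout.  Features that need at least two taps propagate as NaN
markers, never silent zeros.

Two conventions are worth stating because the device's internal algorithm
is unknown: a contact counts as a tap only when flanked by detected peaks
on both sides, so the opening and closing contacts of a trial are not
counted (cell means sit ≈2 below a raw contact count; all comparisons are
unaffected); and "total traveling distance" is the aperture path length,
not doubled per finger.

## Group statistics

Sex ratios are compared with an uncorrected Pearson chi-square.  The
eight per-hand parameters get a three-way mixed ANOVA (between: group;
within: hand, task), the phase SD a two-way mixed ANOVA (within: task).
Because every within factor has two levels, the package computes the
Type-III (unweighted-means) tests exactly via the univariate contrast
reduction: each within effect collapses to one contrast score per subject;
its unweighted-grand-mean test gives the within main effect (df 1, N−k),
a one-way ANOVA of the scores gives its interaction with group, and a
one-way ANOVA of the subject means gives the between effect.  No
sphericity correction is needed at two levels.  Type III matches the
default of the commercial software the reference analysis used; with
unequal group sizes it differs from weighted-means packages only in the
within main effects (the balanced case is identical, which is how the
implementation is cross-checked against `pingouin`).

Bonferroni post-hoc tests run only for significant effects (α = 0.05):
pairwise group contrasts use a pooled error term over all groups
(df N−k) with adjusted p = min(1, raw × number of contrasts); two-level
factors use the paired contrast (family 1); interactions are followed up
by simple effects in both directions, with the family defined per simple
effect.  Analyses are complete-case.  Pearson correlations between age
and every (task, hand, parameter) cell round out the comparison.

## ROC age cutoffs

The reference protocol defines no binary state variable, so the package
makes the rule explicit and configurable: by default a participant is
"low performance" on a parameter when they fall on the worse side of the
whole-sample median (ties to the better class; each parameter's direction
follows the protocol's published better/worse reading), with an
alternative `young_ref_1sd` rule (worse than the young-adult mean by more
than one young-adult SD).  The rule in force is recorded in every output
row.  One noted tension in the source material: the published direction
list calls smaller fatigue slopes better, although its own fatigue
description implies the opposite; the panel parameters are unaffected
because the slope never qualifies for the ROC stage.

Eligibility follows the published rule — only parameters whose Bonferroni
pairwise group contrasts are all significant in both tasks enter the
panel.  Age is the predictor of low performance: AUC by Mann–Whitney
concordance (ties count half), standard error by Hanley–McNeil (the
plausible nonparametric default of the reference software; an assumption),
95% CI as AUC ± 1.96 SE clipped to [0, 1], and the cutoff as the midpoint
between adjacent distinct ages maximizing Youden's J = Sn + Sp − 1 (ties
toward the lower cutoff; midpoints are the only convention that can
produce the published half-year cutoffs from integer ages).  Reported
precision follows the published panel: AUC/CI/J at 2 dp, SE at 3 dp,
cutoffs at 0.1 y, Sn/Sp in % at 1 dp, with half-up rounding.

The published panel's own AUCs are *not* a reproduction target: its state
variable is unrecoverable from the text, and the raw data are private.
The package ships those printed values only as inputs for arithmetic
consistency checks (the Youden identity holds at 2 dp on all 12 rows; CI
reconstruction from the printed AUC/SE matches within one printed digit,
exactly on the headline row).

## Verification strategy and problem sizes

* **Oracle equivalence.** On 500 randomized synthetic trials, all nine
  parameters equal independent naive-loop reimplementations (including
  peak prominence and the V-fit) to 1e−9 relative tolerance; AUC and
  Youden cutoffs equal exhaustive pair/threshold search on 1000 random
  instances (n ≤ 50).
* **Parameter recovery.** A study of 200 subjects per group compares
  extracted cell means against the generating values in all 42 cells.
  Targets for counts, intervals and phase SD come from a direct
  Monte-Carlo draw of the generating contact process (3000 replicates per
  cell), independent of rendering and detection; this also absorbs the
  small-sample behaviour of the per-trial circular-SD estimator (≈1°
  below the population value at ~25 angles per trial).  Amplitudes are
  tested as per-subject residuals against each subject's own generated
  mean, isolating the measurement path from shared cohort-sampling noise.
  The 42 correlated comparisons use the multiplicity-adjusted bound
  |z| < 3.2 (0.05 familywise); headline cells are held to 2 SE.  A
  per-cell 2-SE rule across all 42 tests would fail on roughly half of
  all seeds under its own null, which is why the familywise form is used.
* **Calibration.** Under a null generator (every group, task and hand
  shares one profile), each mixed-ANOVA effect and the Bonferroni
  post-hoc family reject at 0.05 ± 0.02 across 1500 simulated cohorts of
  6 subjects per group — small cohorts keep the run inside a few minutes
  while the F tests remain exact, since the per-trial features are means
  over ~40 taps and hence very close to normal.
* **Determinism.** Identical config + seed reproduce every output file
  byte for byte; ingest mode on exported trial files reproduces
  simulate-mode results exactly (trial CSVs are written at `%.17g`, which
  is lossless for doubles).

The default end-to-end run (421 participants, 842 trials at 100 Hz × 15 s)
completes in well under a minute on one CPU.

## Known limitations

* Left-hand timing is derived from the right hand, so the small printed
  left/right differences in interval means and counts are not reproduced
  (only variability-based hand asymmetries are).
* The published F values, correlation coefficients and AUCs arise from
  private raw data and a partially unspecified protocol; the package
  reproduces the procedures and the qualitative orderings, plus the
  printed-arithmetic identities, not those exact numbers.
* The printed interval means (2 dp) and tap counts are mutually
  inconsistent at the third digit; the generator anchors on the interval
  column, and recovery targets come from the generator's own contact
  process rather than the printed counts.
* With 421 simulated participants, *every* parameter separates all three
  groups (the generator's cell means all differ), so the simulated ROC
  eligibility set is wider than the published three parameters; the panel
  can be restricted explicitly, as `scripts/acceptance.py` does.
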