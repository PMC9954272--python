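# Methods

This note documents the models, conventions and numerical choices behind
`sepscreen`: what exactly is computed from a trial log, what the synthetic
generators emulate (and what they do not), and where the design was
genuinely open.

## Scene model and conventions

The evaluation scene is a 2D screen (default 2560 × 1600 px) with the
sphere starting below a transverse obstacle and four target cubes around
it; the top cube lies above the obstacle, so finishing requires at least
one crossing. Coordinates use a bottom-left origin with y upward — the
game-engine convention — so "above the obstacle" is `y > obstacle_y_px`.
All distances are in px and times in s. Acquisition constants are fixed by
the paradigm: 120 s cap, 60 Hz sampling, hence at most 7200 samples per
trial. The cube/obstacle placement is **not** published; the package
default (start (1280, 500), cubes at (480, 500), (2080, 500), (1280, 150),
(1280, 1250), obstacle midline y = 850 spanning x ∈ [880, 1680]) is a
configurable package choice. Consequently absolute distance-marker
magnitudes from the trial simulator are not comparable to clinical
values — only the cohort-level generator, calibrated directly to published
summaries, is.

## Biomarker definitions and edge rules

* **Te** is the fourth elimination time for complete trials; incomplete
  trials are capped by the paradigm, so Te = 120 s and every biomarker
  whose defining event is absent is reported *missing*, never zero.
* All step sums truncate at the Te sample index; post-completion drift is
  excluded.
* **Crossing** is decided on the sphere-center y coordinate only (the
  obstacle's x-extent is ignored): the first step i → i+1 with
  y\_i ≤ y\_obs < y\_{i+1} defines T\_crossing = t\_{i+1}; later dips below
  do not reset it.
* **Above-obstacle quantities count steps, not samples**: a step
  contributes 1/SR to ET\_above and d\_i to ED\_above only when both of its
  endpoints are above the midline. Treating time and distance by the same
  both-endpoints rule makes the orderings ET\_above ≤ ET\_crossing ≤ Te and
  ED\_above ≤ ED\_crossing ≤ MED\_total exact identities (a sample-count
  time rule would overshoot ET\_crossing by one sampling period whenever a
  trial ends above the obstacle without dipping below). The boundary error
  of ignoring sub-sample interpolation is at most one 60 Hz step.
* **MEE\_first** divides the pre-first-elimination path length by the
  contact-adjusted shortest distance ‖cube − start‖ − (r\_sphere +
  half\_cube), so an ideal straight approach scores exactly 1; published
  medians near 1.03–1.04 are consistent with a ratio floored near 1.
  Start positions inside the contact zone are rejected as degenerate.

## Trial-level simulator

The agent emulates the task, not the physiology: a waypoint-pursuit
controller accelerates the inert sphere toward the current goal with
bounded acceleration `max_accel_px_s2`, velocity damping `damping_per_s`
(terminal speed = accel/damping), and an angular steering error
(SD `steering_noise_sd_rad`) resampled at each replan tick. Crossings are
routed around the obstacle ends; a step that would pierce the segment is
stopped at the midline. Impairment knobs: `detour_prob` inserts spurious
waypoints per replan (wandering), `dwell_above_s` adds one loiter above
the obstacle after the first crossing, and a slower/noisier profile
lengthens everything. Unreached waypoints time out after 4 s, so weak
profiles produce valid incomplete logs rather than deadlocks.

Defaults were chosen once for realism: the unimpaired profile (accel 900
px/s², damping 2.5/s, noise 0.10 rad, detour 3%) completes in ≈ 20 s
median; the impaired profile (accel 800, damping 2.8, noise 0.28, replan
0.4 s, detour 8%, dwell 1.5 s) in ≈ 45 s with ≈ 95% completion — matching
the qualitative picture of a task nearly everyone finishes inside 2 min
with impaired participants slower and less efficient. The simulator is
used to validate extraction (determinism, monotone response to knobs,
oracle equivalence), not to reproduce clinical marker magnitudes.

What it does not model: touch biomechanics, the steering-wheel UI,
learning effects across the training level, pauses/hesitations unrelated
to navigation. Passing trajectory-level tests therefore demonstrates
correctness of the extraction pipeline, not behavioral realism of any
particular clinical population.

## Cohort-level generator

Continuous markers (times, distances, ratios) use log-normal marginals
calibrated to published median [P25, P75] summaries by
μ = ln(median), σ = (ln P75 − ln P25) / (2 · Φ⁻¹(0.75)).
This matches the median and the quartile *ratio* exactly; when a printed
triple is asymmetric on the log scale (e.g. 1.12 [0.78, 1.75]), no
two-parameter log-normal can additionally match each quartile — the
fitted P25/P75 then deviate from the printed ones by the asymmetry
(up to ~4% across the packaged presets). MMSE uses a normal calibrated the
same way, rounded to integers and clipped to [0, 30]; the hard ceiling
compresses the control group's upper tail, which slightly sharpens
group separation relative to the latent normal. Time-rate markers are
capped at 1 (the paradigm's own bound). Age and education are rounded
normals; sex is assigned to the calibrated female fraction up to rounding.

Variables couple through a Gaussian copula on the latent normals.
Between-marker correlations are nowhere published, so the default is
independence; any nonzero `copula_corr` is a modeling assumption and the
spec dict records it. One master seed drives everything: per-group (and
per-trial) sub-streams are spawned from `numpy.random.SeedSequence`, so a
seed fully determines the output.

## Statistics

* Group comparison uses the tie-corrected Kruskal–Wallis H with a
  chi-square(1) reference — for two groups this is the Wilcoxon/
  Mann–Whitney rank-sum test up to the reference law. Degenerate input
  (all pooled values identical) returns H = 0, p = 1.
* The 2×2 test is Pearson chi-square without continuity correction
  (switchable); a zero marginal is reported as undefined (NaN).
* No multiplicity correction is applied to the comparison table; the
  report records the number of tests performed.
* ROC scores are oriented so higher = impaired: markers with MCI median
  above NC median pass through, others (MMSE) are negated; the report
  notes the orientation. AUC is trapezoidal, identical to the midrank
  Mann–Whitney estimator.
* **Step-up selection** is pure forward logistic selection with
  likelihood-ratio entry tests and no removal step. The entry threshold
  is familywise-controlled: with m candidates remaining, the best
  candidate enters only if its LRT p < 0.05/m (Bonferroni per step).
  A flat per-candidate 0.05 would admit a spurious marker in
  1 − 0.95⁸ ≈ 34% of null steps, i.e. it could not deliver a ≤ 5%
  false-inclusion rate; the adjusted rule holds the per-step familywise
  entry chance at 5% while leaving genuinely informative markers
  (entry p ≪ 10⁻³ at realistic effect sizes) unaffected. The flat rule
  remains available (`familywise=False`).
* Perfect or quasi-separation in a logistic fit triggers a
  ridge-stabilized refit (L2 penalty 10⁻⁴, unpenalized likelihood
  evaluated at the ridge solution) and flags the selection result.
* The combination score is the fitted logistic linear predictor over the
  selected markers; for a single marker this is a monotone map, so its
  AUC equals the marker's.
* The basic-education subgroup keeps rows with strictly more than 9 years
  of education. (Published subgroup tables paradoxically show an MCI
  education P25 of 6 years under the same rule; the package implements
  the stated strict rule.)

## Problem sizes and tolerances

The verification suite checks extractor-vs-oracle equivalence and
ordering invariants on 1000 random simulated trials at 10⁻⁹ relative
tolerance; AUC against exhaustive pair counting on 400 random ≤ 8-point
datasets; rank-sum p-values against a 10⁵-draw permutation (mid-p) oracle
at n = 20+20 within Monte-Carlo error plus a 0.005 allowance for the
chi-square reference's own finite-sample error; generator round-trips at
n = 10⁴ per group within 2% (median and quartile ratio, see above;
integer resolution for MMSE); selection operating characteristics over
100 seeded cohorts of 200 per group; and the published screening AUCs on
20 calibrated cohorts of 500 per group (50 cohorts of 46 + 46 for the
completion-time share).

## Known limitations

* Trajectory-level marker magnitudes depend on unpublished scene
  geometry; only cohort-level (calibrated) quantities are comparable to
  clinical values.
* The log-normal/copula cohort model captures marginal location and
  spread but not the true joint dependence between markers, nor
  non-log-normal tail behavior.
* The agent model is a behavioral abstraction; its impairment knobs are
  not validated against patient kinematics.
* Education, age and MMSE are sampled independently within group, so
  education-stratified analyses on synthetic cohorts inherit no
  education-cognition correlation.
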