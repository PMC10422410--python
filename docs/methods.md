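# Methods

`etmt` scores screen-based trail-making sessions recorded with an eye
tracker.  A participant views four stimuli in turn — an 8-target and a
25-target number trail (TMT-A simple/complex) and an 8-target and a
24-target alternating number–letter trail (TMT-B simple/complex) — and is
asked to look at the targets in ascending order.  The package turns the raw
gaze stream into 13 features, two Mamdani fuzzy scores (visual search speed,
focused attention), and one trained cognitive-impairment score.

## Fixation detection

Raw gaze logs carry 60 Hz samples (timestamp in ms, screen position in
pixels, optional pupil diameter, validity flag).  Fixations are found by
dispersion-threshold identification (I-DT): a fixation is a maximal run of
consecutive valid samples whose bounding-box width + height stays within
`dispersion_px` (default 50 px) and whose span is at least `min_duration_ms`
(default 100 ms).  Invalid samples split runs rather than being
interpolated — conservative, and it keeps the detector deterministic and
idempotent.  Defaults suit a desktop display at 50–60 cm viewing distance;
both are configurable because the appropriate dispersion scales with screen
geometry.

## Stimulus layouts

Each target is a disc-shaped area of interest (AOI), default radius 40 px.
Layouts are drawn by seeded uniform rejection sampling with a minimum
center separation of 2.5 × radius (bounded at 10,000 retries, failing
loudly on impossible canvases), so AOIs never overlap and hit-testing is
unambiguous; a point exactly on the boundary circle counts as inside.  The
expected visiting order is ascending numbers for TMT-A and the standard
1-A-2-B-… alternation for TMT-B.

## The 13 features

Low level (per trial, from fixations): FL1 fixation count, FL2 total
fixation time (ms), FL3 = 100·FL2/trial duration, FL4 = FL2/FL1 (0 when no
fixations).

Middle level (per AOI): FM1 dwell time, FM2 = 100·FM1/trial duration, FM3
glance count, FM4 revisits = (distinct visit runs − 1, floored at 0) where
a visit run is a maximal streak of consecutive fixations in the same AOI,
and FM5 first-fixation duration.

High level, from the scanpath string — the ordered AOI labels under
successive fixation centroids with consecutive duplicates collapsed (a
multi-fixation dwell is one visit; the raw uncollapsed string is available
behind a flag):

* **FH1, scanpath score** — token-level Levenshtein distance between the
  collapsed scanpath and the expected sequence, unit edit costs.  Tokens
  are atomic, so the two-character label "12" costs one edit, not two.
* **FH2, total time** — trial span in ms; session value is the sum over the
  four trials (per-trial values remain available).
* **FH3, error count** — out-of-AOI fixations plus wrong-order visits.
  Wrong-order visits are counted by an expected-sequence pointer walk over
  the collapsed scanpath: a token matching the next expected label advances
  the pointer, anything else counts one error.  Missing (never-visited)
  targets are not double-counted here; they already surface in FH1.
* **FH4, inattentional blindness** — the count of replayed visit runs: a
  left-to-right scan that, at each position, looks for the longest run of
  ≥ 2 tokens that already occurred earlier, counts one event, and skips
  past it.  The minimum length of 2 separates genuine replays of a stretch
  of targets from single-target revisits, which FM4 already measures.

Per-participant aggregation over the four trials: counts and times (FL1,
FL2, FM1, FM3, FM4, FH1–FH4) are summed — FM values over AOIs first —
while percentages and per-event durations (FL3, FL4, FM2, FM5) are
averaged; FM2 and FM5 are averaged over all AOIs of a layout, zeros
included, so the statistic does not depend on which AOIs happened to be
hit.  A participant missing a trial is aggregated over the trials present
and flagged in the report's provenance rather than rejected.

## Fuzzy scoring

Both scoring systems are two-input Mamdani systems with three trapezoidal
sets per variable and the full 9-rule grid; AND = min, implication = min,
aggregation = max, defuzzification = centroid on a uniform grid (step 1e-3
on the unit output universe).  Inputs are normalized to [0, 1] first:
FH1 and FH3 by the session's expected-sequence length (65 for the full
battery, capped at 1), FH2 by a 180 s reference ceiling (slightly above the
longest whole-battery completion time we would expect from an unimpaired
desk session), FH4 saturating at 3 events.

The rule matrix maps low "badness" in both inputs to a High score and high
badness to Low, with the mixed cells graded in between; it is symmetric in
the two inputs and overridable in the JSON config, as are all breakpoints.

Input sets are Low = (0, 0, 0.2, 0.4), Medium = (0, 0.2, 0.6, 0.8),
High = (0.4, 0.6, 1, 1): an overlapping-plateau partition in which each
set's falling edge lies entirely under its neighbour's plateau, so the
pointwise-max membership is 1 everywhere.  This is deliberate: with the
more common partition whose adjacent sets cross at membership 0.5, the
aggregate's clip height dips mid-transition wherever two neighbouring rules
share a consequent, and the centroid then slides back up — a local
non-monotonicity of about 0.02 that contradicts the intended semantics
(more errors can never raise a score).  With the overlapping plateaus the
centroid-defuzzified score is non-increasing in each input across the whole
universe (verified on an 11 × 50 grid in the tests).  Output sets are the
conventional Low = (0, 0, 0.2, 0.4), Medium = (0.2, 0.4, 0.6, 0.8),
High = (0.6, 0.8, 1, 1).

If the aggregate is identically zero — possible only with a misconfigured
universe, since the shipped sets cover it — the universe midpoint is
returned with a degenerate flag rather than NaN.

Scores are banded at thirds of [0, 1].  Deficit indications mirror the
bands: low visual search speed grades the processing-speed and
visual-attention deficits "high", and low focused attention does the same
for the five attention-linked deficits (motor impairment, attentional
disengagement, memory, neuropsychological impairment, executive
functioning).

## Cognitive-impairment score (ANFIS)

Absent clinician labels, targets come from k-means (k = 3, k-means++
seeding, 10 restarts, fixed seed) on the z-standardized 13-feature vectors.
Clusters are ordered by the ascending mean of standardized FH2 + FH3 —
slower and more error-prone means more impaired — and labeled 0 / 0.5 / 1.
The encoding and the ordering statistic are conventions of this package;
both matter only up to the monotone ordering of the three groups.

The network is a first-order Takagi–Sugeno system with **scatter
partitioning**: one rule per cluster, each rule holding a Gaussian
membership per input (center = cluster mean, width = cluster sd floored at
0.1 in standardized units) and a linear consequent (initialized to zero
weights with the cluster label as intercept).  A grid partition with three
sets per input would enumerate 3^13 ≈ 1.6 M rules for 13 inputs, which is
neither tractable nor meaningful at cohort sizes of tens; "three membership
functions" is realized as three rule-wise sets per input.

Training is the classic hybrid loop on a label-stratified 75/25 split
(plain shuffled split when targets are continuous): per epoch, (1) all
consequent coefficients are solved globally by least squares on the
firing-strength-weighted design matrix (ridge 1e-8 for conditioning), then
(2) one full-batch gradient step (rate 0.01) updates premise centers and
widths against squared error, widths never dropping below the floor.
Default 30 epochs.  A final least-squares solve follows the last gradient
step so reported errors reflect optimal consequents for the final
premises.  Error statistics are RMSE, mean error, and sample (n−1) standard
deviation of actual − predicted.  When the total firing strength underflows
(an input far outside every rule), the forward pass falls back to the
nearest-center rule instead of dividing by zero.  The final score is
clipped to [0, 1] and banded at thirds.

## Synthetic sessions

The simulator emulates the behavioral signatures the features measure, not
oculomotor physiology.  An ideal observer dwells on each target in order
(truncated-normal dwell, mean 250 ± 50 ms, floored above 50 ms so every
planned fixation survives detection defaults; 150 ms transits) while 60 Hz
samples are emitted with Gaussian jitter (5 px default).  Impairment knobs:
`stray_prob` inserts a stray fixation per transition (60 % wrong target,
40 % background, so both branches of FH3 are exercised), `revisit_prob`
replays the previous two visited targets (the FH4 event), and
`slow_factor` dilates all times.  The default low / medium / high profiles
(stray 0.02/0.15/0.35, revisit 0.01/0.15/0.35, slow 1.0/1.5/2.5) give
clearly separated groups while overlapping enough that recovery is not
trivial.

What passing tests on simulated cohorts do show: the full pipeline is
coherent — features respond monotonically to their driving behaviors,
k-means recovers planted groups, and the trained impairment score orders
the groups correctly.  What they do not show: performance on real
recordings, where fixation segmentation noise, calibration drift, blinks,
and individual strategy variation all blur the feature distributions.

## Numerical and degenerate-input choices

* Fixation detector: ties broken by greedy left-to-right maximal runs; a
  run shorter than the duration threshold advances one sample, not past the
  window.
* Levenshtein: iterative two-row dynamic program; distances are exact
  integers.
* Centroid integration: trapezoidal rule on the 1e-3 grid; agreement with a
  10×-finer independent oracle is tested to 1e-3.
* k-means degenerate data (< k distinct vectors) and empty clusters raise
  instead of silently collapsing rules.
* All randomness flows through explicit integer seeds (numpy
  `default_rng` / `SeedSequence`, scikit-learn `random_state`); identical
  seeds give byte-identical feature tables, models, and reports.

## Problem sizes in the shipped experiments

The cohort experiments use 30 simulated participants (10 per group, 120
trials); the function-recovery experiment uses 200 samples from a known
2-input, 2-rule Takagi–Sugeno generator with noise sd 0.01, inputs drawn
around the two rule prototypes — the cluster-concentrated regime a
scatter-partitioned system assumes — and premises initialized by k-means on
the inputs, as in the cohort workflow.

## Known limitations

* The fixation-detection parameters of commercial analysis suites are
  proprietary; real recordings segmented elsewhere can be supplied as
  pre-detected fixation tables to bypass the built-in detector.
* Session-level normalization ceilings (180 s, blindness cap 3) are
  conventions; strongly atypical populations may need different scales.
* Saccade-, blink-, and pupil-based features are out of scope.
* The impairment score is a screening aid trained on unsupervised labels;
  it is not a diagnosis.
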