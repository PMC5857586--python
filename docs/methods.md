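# Methods

`gazepipe` reimplements, as a tested pipeline, an individual-differences
eye-tracking analysis for infants: how quickly gaze arrives at the goal of an
observed feeding action (action prediction), how strongly the pupil dilates
when a social interaction ends inappropriately (action evaluation), how early
a reach toward a moving toy is launched (motor development), and the
correlations that link the three. Because no raw infant data are available,
the pipeline is validated end-to-end on synthetic cohorts with known ground
truth. This note records the models, the parameters that matter, and the
design choices made where the published procedure leaves the design open.

## Fixation filter

Gaze at 60 Hz is segmented with the classic two-parameter windowed-velocity
filter. The velocity at sample *i* is the Euclidean distance between the mean
gaze position of the `window` samples before *i* and of the `window` samples
from *i* onward, in pixels per window. The two published parameters are the
velocity threshold (35 px/window) and the centroid-distance merge threshold
(35 px).

Design choices where the procedure is underdetermined:

- **Window length** — not published; default 5 samples (the classic
  implementation's default), configurable.
- **Boundary placement** — each maximal run of super-threshold velocity
  contributes one fixation boundary at its (first) velocity maximum. This is
  the Olsson-style peak rule of the original filter. A naive
  "below-threshold-runs-are-fixations" rule would bias every detected onset
  late by roughly one window (~83 ms at 60 Hz), because the symmetric
  two-mean velocity stays elevated for `window` samples after a saccade
  lands; the peak rule recovers onsets to about one sample, which the
  latency-recovery tests confirm. Within a run, the boundary is the first
  sample within 1e-6 px/window of the run maximum, so exact velocity plateaus
  are not decided by floating-point round-off.
- **Invalid gaze** — runs of invalid samples always terminate a fixation.
  Centroid merging may bridge an invalid gap only when the gap is shorter
  than `window` samples; merged centroids are recomputed over all member
  samples (gap samples are never members).
- **Minimum duration** — default 1 sample: the published procedure states no
  minimum and none is silently imposed.

## Action-prediction scoring

Two rectangular AOIs (bowl, mouth), each 6.3 × 3.8 visual degrees, are
converted to pixels with extent = 2·D·tan(θ/2) per axis through the screen's
mm-per-pixel density. The monitor's physical size and viewing distance are
not published; defaults (1920×1080 px, 509×286 mm, 600 mm) are explicit
assumptions in the geometry config. AOI membership is decided by fixation
centroid, tying AOI entry to the fixation filter rather than to single
samples.

A trial is scored when (1) a bowl-AOI fixation overlaps [food pickup, spoon
leaves bowl], and (2) within [spoon leaves bowl, arrival + 1 s] a bowl-AOI
fixation is followed (strictly, by onset) by a mouth-AOI fixation. The
dependent variable is (first qualifying mouth-fixation onset − arrival) in
ms; negative = predictive. A fixation that begins before a window but
persists into it counts, with latency measured from its onset — the onset is
the only unambiguous "time at which the infant fixated", so latencies
slightly below −(transport time) are possible in principle. Participants need
≥ 2 scored trials; included participants with negative mean latency are
classified predictive, otherwise reactive.

## Pupillometry

Both eyes' diameters are averaged where valid (single eye used when only one
is valid) — standard practice; the published procedure does not state eye
handling. Cleaning then applies four steps strictly in order:

1. samples outside 2.5–5.5 mm removed (bounds retained);
2. samples differing by more than 1 mm from the previous **retained** value
   removed — referencing the last surviving value rather than the raw
   neighbour so a removed spike cannot cascade into rejecting everything
   after it;
3. interior missing runs shorter than 10 samples linearly interpolated;
   longer runs and edge runs left missing;
4. a 10-sample moving average. An even window cannot be centered exactly; the
   window is [i−5, i+4], truncated at edges and never crossing a missing
   gap, and output stays missing where input is missing.

Step order is observable (smoothing before interpolation gives different
numbers) and is regression-tested against a per-sample reference
computation.

Each giving trial is scored as the mean pupil over [grasp, grasp + 3 s) minus
the mean over [grasp − 1 s, grasp). A window is usable when ≥ 50% of its
samples are retained (the published criteria give only the ≥ 3-trials rule;
some per-window validity rule is necessary and this one is explicit and
configurable). The participant score is mean change on inappropriate minus
appropriate trials, requiring ≥ 3 valid trials per condition.

## Reach scoring

The 3 cm movement rule and follow-event requirements are human-coder inputs
(booleans); the module only computes latency = reach onset − midline
crossing on trials that pass both the attention and reach-validity flags.
Slow-object trials are removed (they showed no association with the other
measures); the participant mean uses fast trials only, and a single valid
fast trial suffices for inclusion, matching the reported 1–2-trial range.

## Statistics

One-sample, paired and pooled-variance two-sample t-tests (integer dfs match
the n₁+n₂−2 convention; Welch behind a flag), two-sided p-values, no
multiple-testing correction (none was applied in the original analysis).
Correlations are Pearson with pairwise deletion, so every cell reports its
own n. Before correlating, variables are oriented so high performance is
positive: both latencies are negated, the dilation difference is kept.
Skewness is the adjusted Fisher–Pearson coefficient. Degenerate inputs
(zero variance, fewer than 2 complete pairs, n < 3 per cell) raise or mark
the cell not-computable instead of returning infinities.

## Synthetic cohort

The generator emulates the statistical structure the analysis assumes, not
gaze physics. Latent abilities (prediction ms, dilation mm, reach ms) are
trivariate normal; correlations are configured on the oriented scale with
published 6-month defaults (0.34, 0.33, 0.12). Means are the published group
means (−40 ms, 0.063 mm, −380 ms); SDs are recovered from printed standard
errors as SE·√n (≈ 418 ms, 0.139 mm, 357 ms). A Student-t option exists for
robustness exercises.

Per trial:

- **Eating trials** (9 s; pickup 2.0 s, leaves bowl 4.0 s, arrival 5.5 s):
  bowl fixation with Gaussian jitter (2 px, far below the velocity
  threshold), a 2-sample saccade, then a mouth fixation with onset at
  arrival + θ_pred + N(0, 150 ms). The per-trial latency is truncated to
  what the event geometry can express ([−1.45 s, +0.9 s]); with the default
  spread this touches < 2% of trials.
- **Giving trials** (9 s; grasp 2.5 s): pupil = baseline N(3.5, 0.2) mm +
  gamma kernel (mode 1.2 s, shape 2) × θ_eval on inappropriate trials only,
  + N(0, 0.05) mm per sample. The kernel is normalized so its mean over the
  3 s analysis window on the 60 Hz grid equals 1, making the amplitude
  parameter equal to the expected baseline-corrected change score — the
  quantity recovery tests compare. The kernel is a generator-side
  assumption; the scoring side never sees it.
- **Reach trials**: 3 slow then 3 fast; onset = midline + θ_motor +
  N(0, 100 ms).

Artifacts: blinks at 0.10/s with geometric lengths (mean 6 samples), pupil
spikes to 5.8–7.5 mm at 0.05/s, and per-task trial dropout (0.42 eating,
0.07 giving, 0.55 reaching) chosen to reproduce the published data yield
(~3.5 of 6, ~5.5 of 6, ~1.4 of 3 valid trials). Dropout is modelled at the
trial level only; whole-session losses (failed calibration, fussiness) are
not modelled, so cohort-level exclusion percentages sit below the published
ones even though per-included-participant trial counts match. All randomness
derives from `SeedSequence` streams keyed by (seed, stream, participant,
trial), so any subset of a cohort regenerates identically and outputs are
byte-stable.

What the generator does **not** emulate: saccade main-sequence dynamics,
smooth pursuit, luminance-driven pupil changes, pupil foreshortening, shared
method variance between tasks, or age differences in artifact structure.
Passing recovery tests therefore shows the scoring chain is faithful to its
own definitions and unbiased under this noise model — not that it would be
unbiased under every property of real infant data.

## Numerical choices and validation sizes

- Velocities and window means use cumulative sums; equality with naive
  loop-based computation is enforced to 1e-9 px (exact boundary agreement)
  on randomized traces.
- Noiseless latency recovery is exact to well below one sample period
  (tested at ±16.7 ms over embedded latencies −500…+200 ms).
- Noiseless dilation recovery through the full cleaning chain is accurate to
  ~1e-4 mm — the residual is the moving average's edge effect at the window
  boundaries, which is inherent to the published smoothing step; without
  smoothing the change score equals the kernel's window mean to 1e-9.
- Correlation recovery uses 500 replicates of 78-participant cohorts at a
  true oriented correlation of 0.34 (mean recovered r within ±0.05); null
  calibration uses 1000 replicates at ρ = 0 (rejection rate 3–7% at
  α = .05). These replicate counts put Monte-Carlo error well below the
  tolerances while keeping a full validation run under ten minutes on one
  core.

## Known limitations

- The fixation filter's boundary rule reconstructs the named vendor filter
  from its published description and parameters; vendor-exported fixations
  could differ at boundary samples.
- The moving-average behaviour at missing-data boundaries (truncation, never
  crossing a gap) is one defensible reading of an underdocumented step; it
  is config-exposed rather than claimed as the original behaviour.
- The Vineland motor covariate is treated as an optional external column;
  its internal scoring is out of scope.
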