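# Methods

This note documents the models, conventions and numerical choices behind
`sonolift`, and what the synthetic-data tests do and do not establish about
real recordings.

## Coordinate and file conventions

Coordinates are right-handed, millimetres, z vertical (up), x anteroposterior
(positive toward the athlete's front); frames are 0-based with
`time = start_time + frame / frame_rate`. Captures are plain text in two
dialects: `tsv_wide` (header lines `#FRAME_RATE`, `#START_TIME`, optional
`#ZERO_IS_MISSING`, then one row per frame of x/y/z triplets) and `csv_long`
(`frame,time,marker,x,y,z`; the frame rate is inferred from the median time
step). Occlusions are blank cells (wide) or absent rows (long); the
`(0,0,0)`-as-missing convention some motion-capture exporters use is honored
only when the header flag says so, because origin-adjacent points are
legitimate data. No public schema exists for the original recordings, so this
schema is a documented stand-in. Floats are written in shortest
exact-round-trip decimal form, so write→read is lossless.

Gap filling interpolates interior occlusion runs of at most `max_gap_frames`
linearly per coordinate; edge gaps are never filled (no extrapolation). The
operation is idempotent.

The stored per-session record has one row per 10 ms control frame: time, all
marker positions, sb, bfd, the distortion level (the quality value fed to the
degradation effect) and the right/left output volumes. Right = surround
array, left = frontal speakers — the left/right naming preserves the original
channel routing; the library API uses the portable names front/surround.
Control (no-sonification) sessions leave the three audio columns empty.

## Kinematics

**Spine bend** is the vertebral chain length `|L4−T12| + |T12−T7| + |T7−C2|`
(mm), invariant under rigid motion by construction.

**Barbell–foot distance** projects all points to the floor plane and measures
the perpendicular distance from each front-foot (toe) marker to the infinite
line through the barbell extremities, keeping the foot with the smaller
magnitude. Perpendicular point-to-line distance (rather than distance along
the anteroposterior axis) is the default because it is robust to barbell yaw;
an axis-projected variant is available via `mode="axis"` for comparison, and
the two coincide when the bar is perpendicular to the axis. The sign comes
from a `rearward_axis` — a horizontal unit vector pointing from the toe
markers toward the athlete's body, estimated at calibration as the horizontal
direction from the mid-foot point to L4. With that orientation the setup
position (bar over mid-foot, behind the toe markers) measures positive and a
bar past the toes negative, which is what makes `bfd = 1` at setup and
`bfd < 0` beyond the toes. Ties between the two feet need no special case
(min of equal values).

**Calibration** takes the median of the relevant quantity over the *central*
1.0 s window of a static capture: the centre avoids settle-in and release
transients, the median resists marker jitter, and 1 s (100 frames) is ample
for a held pose. A pose fails loudly if the capture is shorter than the
window or the required markers are valid in fewer than half the window
frames. With 2 mm marker noise the calibrated chain length is reproducible
to well under 1 mm.

**Missing data**: any frame with a required marker occluded yields NaN in
every derived column; NaNs are excluded from per-repetition and session means
and held over by the audio renderer. They are never silently interpolated at
this stage (use `fill_gaps` explicitly).

## Sonification

The transfer function `y = 1 − 1/(1 + exp(−α(x−β)))` is evaluated via the
numerically stable logistic (`scipy.special.expit`), strictly decreasing with
`y(β) = 0.5` and the exact symmetry `y(β+δ) + y(β−δ) = 1`. Defaults:
spine `(α=10, β=0.2)`, barbell `(α=15, β=0.6)`. Two consequences worth
knowing:

* At a perfectly neutral spine (sb = 0) the quality is ≈ 0.881, not 1 — the β
  margin is a design feature (distortion-free slack around neutral), so the
  library does not clamp it; a renderer-level perceptual floor flag exists but
  is off by default.
* In double precision y saturates to exactly 0 or 1 once |α(x−β)| exceeds
  ≈ 36; the mathematical open-interval/strict-monotonicity properties hold on
  the resolvable domain, which covers every physically plausible input.

The barbell channel outputs `gain_front = y`, `gain_surround = 1 − y`; the
two always sum to 1 (counterbalanced crossfade).

**Offline rendering.** The original degradation effect ran inside a
proprietary DAW patch; this renderer defines degradation as sample-and-hold
decimation with hold length `round(1 / max(quality, q_min))` samples
(`q_min = 0.01` caps the worst-case hold at 100 samples), which reproduces the
metallic aliasing character deterministically: quality 1 is bit-exact
identity, quality 0.5 holds every second sample. The spatial channel
crossfades between a mono downmix (the "narrow frontal" image) and the
original full-width signal: `out = gain_surround·x + gain_front·mid(x)`.
Controls are held piecewise-constant between 10 ms control frames (zero-order
hold, no gain ramps — the live system's smoothing, if any, is unstated);
missing control frames hold the last valid value (neutral before the first).
Output length and dtype always equal the input's; integer audio is rounded
and clipped on the way back.

A streaming deployment is specified as a message contract only: inbound
`(timestamp, marker positions)`, outbound `(timestamp, quality, gain_front,
gain_surround)`, latency budget one control frame (10 ms). No transport is
implemented.

## Segmentation and summaries

The bar height (midpoint of the two extremity markers) is low-passed with a
zero-phase 2nd-order Butterworth at 4 Hz — comfortably above lift tempo
(0.17–0.5 Hz per repetition) and below marker jitter. Lockout peaks are
detected with prominence ≥ `min_amplitude_frac` (default 0.5) × signal range
and separation ≥ `min_period` (default 1 s); each repetition spans valley to
valley around one peak, with half-open spans `[start, end)` so consecutive
repetitions tile without double-counting (a shared valley frame belongs to
the later repetition). A flat signal yields zero repetitions, not an error.
The interior extremum field is named `top_frame` — for bar height the apex of
the lift.

The discard rule removes the first three and last two repetitions (set
transients); a 10-rep session keeps the middle five. The session statistic is
the **two-stage mean** — the unweighted mean of per-repetition means — which
matches "one mean value over five repetitions" and is robust to
repetition-duration variation; a pooled-frames variant is available
(`pooled=True`) because the original splitting script is undescribed and
either reading is defensible. Repetitions entirely missing a quantity are
excluded from that quantity's session mean.

## Statistical pipeline

All tests are two-sided at α = 0.05 with no multiple-testing correction by
default (a Holm helper is provided). Within-group comparisons are **paired**
(the same participants perform control and feedback sessions). The branch
rule is: Shapiro–Wilk on the paired differences (within) or on each sample
(between); normal → paired t / pooled two-sample t (pooled variance as the
era's convention; Welch via `pooled=False`); otherwise Wilcoxon signed-rank /
rank-sum. The branch taken is recorded in the result so any run is exactly
reproducible from its outputs. Zero-variance inputs return degenerate p = 1
results with warnings instead of crashing. Group homogeneity over expertise
uses Pearson χ² without continuity correction.

Expertise enters the nested linear models (null; +feedback; +expertise;
+both, compared by F-tests against the null) as an **unordered** 3-level
factor even though experience levels are ordered, because per-level fitted
means are part of the output and a single ordinal contrast could not produce
three free level means; polynomial (ordinal) coding is available via
`ordinal=True`. An exact fit (zero residual) reports F = ∞, p = 0 rather
than NaN. Ratings (1–7 Likert; 0 = "no feedback perceived", excluded before
testing) are compared between groups with Mann–Whitney U and related to
movement improvement with Kendall's τ-b (tie-corrected).

Improvement sign conventions: `delta_sb = sb(feedback) − sb(control)` where
negative is better; `delta_bfd` likewise where positive is better.

## Synthetic data: what it emulates and what it does not

The generator reproduces the capture conditions — 22 body markers (4 spine,
2 front-foot, 16 kinematically plausible decoys) plus 4 barbell markers at
100 Hz — with exact analytic ground truth. The spine chain has fixed vertical
spacings (150/200/150 mm, the larger middle gap mirroring sport-top
clearance) and a common posterior offset δ of T12/T7; chain length
`2√(150²+δ²) + 200` is invertible in δ, so any target per-frame sb is realized
exactly. The neutral pose carries δ = 40 mm so extension (sb < 0) is
representable down to ≈ −0.21 (the straight-chain floor); fault amplitudes
are clipped there. The bar height follows one raised-cosine cycle per
repetition (mean lift phase exactly ½, so a session's true mean sb is half
its peak amplitude) and the bar's anteroposterior position drifts so true bfd
dips from 1 to the configured minimum at mid-lift. Marker noise is i.i.d.
Gaussian per coordinate; one RNG stream per session keyed by the seed, cohort
session seeds drawn from the cohort seed.

Cohorts default to the study's scale: 16 instruction / 15 sonification
participants, expertise mix (0.16, 0.48, 0.36), control baselines
(mean sb ≈ 0.35 peak-scale ≈ 0.18 session-mean, mean bfd ≈ 0.4), and effects
on the session-mean scale of −0.12 (sd 0.15) for sb and +0.65 (sd 0.70) for
bfd — the magnitudes of the reported movement improvements. Every simulated
session runs through the *full* pipeline (derivation, segmentation, discard,
summary), so cohort statistics inherit all measurement-stage error.

What passing tests therefore show: the kinematic definitions, calibration,
segmentation, mapping and statistics are internally correct and recover known
truth under realistic noise. What they do not show: robustness to
soft-tissue artifact, marker mislabeling, skeleton-model drift, tempo
variation within a set, or genuinely human movement variability — the decoy
markers move rigidly and the faults are smooth by construction. Conclusions
about real athletes require real captures.

## Problem sizes and tolerances

Default sessions are 10 reps × 3 s × 100 Hz (3 000 frames); acceptance-level
simulations use 500 replicates for test-size calibration (±3 percentage
points ≈ 3 binomial SDs) and 11 cohort seeds for power/recovery checks.
Kinematic exactness is asserted at 1e−9 (float64 leaves ~1e−15 headroom),
logistic agreement at 1e−12, text round-trips are exact, and segmentation
boundaries on clean signals match ground truth within 2 frames (20 ms).
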