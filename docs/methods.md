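# Methods

## Data model and conventions

Sessions live in a *room frame*: origin at a corner, x ∈ [0, 6], y ∈
[0, 9] meters by default, matching overhead-camera digitization of a
playroom. Training courses live in a *field frame*: origin at the center
of a 30 × 20 m simulated soccer field. The room is mapped onto the field
by translating the room center to the field center with meters preserved
1:1; an affine override is possible by transforming coordinates before
course construction. Time is in seconds from session start. Step
timestamps must be strictly increasing: in digitized video two feet never
land at the identical frame, so ties are treated as data errors rather
than silently reordered. Out-of-room points are an error by default, with
an optional clamp-to-wall mode for noisy digitizations.

## Bout segmentation

A walking bout ends when the walker is stationary for ≥ 500 ms; we
operationalize this on step events by starting a new bout whenever the
interval between consecutive steps reaches the threshold
(`stationary_threshold`, default 0.5 s, inclusive). Segmentation is a
partition: every step belongs to exactly one bout.

## Variety metrics

All four dimensions are dispersions of within-session quantities:

- *Curvature* (shape). Straightness index chord/arc; for a bout it is the
  unweighted mean of the whole-bout ratio and the mean ratio over all
  overlapping consecutive 3-step windows (sliding window, stride 1). Only
  bouts of ≥ 4 steps have a defined curvature; a bout whose path has zero
  arc length (coincident steps) is undefined, and windows with zero arc
  are skipped. Curvature is bounded in (0, 1] and invariant to rigid
  motions of the coordinates.
- *Heading change* (direction). The plane angle between consecutive step
  displacement vectors, reported as absolute magnitude in [0, 180]°
  — "change in direction" without sign is the conservative reading; a
  `signed=True` option returns the signed angle for turn-bias analyses.
  Zero-length displacements contribute no angle. Direction variety pools
  the step pairs of all bouts (per-bout aggregation is available via
  `pool_direction=False`).
- *Standard errors.* SE = sample SD (n − 1 denominator) / √n, the
  convention of behavioral reporting. A dimension with fewer than two
  contributing values is **undefined and flagged** (`VarietyProfile.flags`),
  never silently zero — a zero would mean "perfectly consistent," which is
  the opposite of "not measurable."

Note a consequence that matters when interpreting profiles: because three
of the four dimensions are standard errors, they confound dispersion with
the number of contributing units. A walker with few bouts has noisier and
systematically larger SEs than a walker with many bouts and the same
underlying SD. This is a property of the metric definition, kept
deliberately; the bout count is itself one of the four dimensions.

## Balanced k-means

Clusters must hold exactly n/k walkers each (n divisible by k is
enforced). The assignment step is a balanced transportation problem: each
centroid owns n/k unit-capacity slots and points are matched to slots
minimizing total squared distance, solved exactly with the Hungarian
algorithm (`scipy.optimize.linear_sum_assignment`) on the point × slot
cost matrix — O(n³), comfortable for cohort sizes in the tens to
hundreds. Alternating exact assignment with centroid means makes the
within-cluster sum of squares non-increasing, so the loop terminates;
iteration stops when the assignment repeats. Initialization is seeded
k-means++ spreading; the best of `n_restarts` (default 32) runs by
objective is kept. Feature columns are z-scored by default (min–max
scaling is provided for display). Determinism: results depend only on the
seed, and the input rows are canonicalized by lexicographic sort
internally, so permuting the cohort (with its ids) yields the identical
partition; cluster indices are renumbered by first canonical member.
On small instances (n ≤ 8, k = 2) the solver provably attains the
exhaustive balanced optimum in the test suite; a greedy capacity-filling
assignment was considered as a fast fallback and rejected as unnecessary
at these problem sizes.

## Course construction

A session becomes an alternating walk/stop timeline: each bout's steps
are walk waypoints with the walker's own timing (the robot's target
updates at the recorded step times), and each inter-bout pause becomes a
stop of min(pause, 2 s) — after about 2 s a humanoid is fully stabilized,
so longer standing adds no training value. From each timeline one
contiguous block of exactly 240 s is sampled:

- the start is uniform over feasible starts; a start falling inside a
  stop advances to the next walking content, so every block opens with
  walking — this guarantees that concatenated blocks never abut
  stop-to-stop, which would otherwise either merge into a stop above the
  2 s cap or break the alternation invariant;
- a timeline shorter than 240 s is traversed cyclically (repeated
  end-to-start) until the duration accumulates;
- a block boundary that bisects a walk leg splits it at the linearly
  interpolated position, so the block duration is exact.

Fifteen blocks concatenate into one 3600 s course. Walk elements carry
both a target and a scheduled duration; giving walk elements a duration
(from step timestamps, or from the heading-update interval for geometric
courses) is what makes total course duration well-defined and exactly
conserved.

Geometric courses: the line walks 10 × 7 s forward segments with 2 s
stops; the circle updates the target heading every 1 s for 20 s then
stops 2 s, 7 repetitions around a fixed circle (default radius 1.5 m);
the square alternates an end-stop lap with a corner-stop lap (5 s of
walking per side, 20 s per lap), 7 repetitions of the alternating pair —
the repetition count is read as pairs, exposed as a parameter. Absolute
sizes derive from the nominal walk speed (default 0.4 m/s, a conservative
humanoid pace): 7 s × 0.4 m/s = 2.8 m line segments, 2 m square sides.
These sizes are design choices; only the temporal structure is fixed by
the training protocol.

## Tournament analytics

League tables are exact recounts: per team, W/L/T from goal comparisons,
points = 3W + T, per-game goal means with SE, and average goal difference
(mean over games of scored − conceded). Ranking ties break by average
goal difference, then name. The ANOVA on goal difference uses one
observation per team per game (so a 5-team, 1,000-games-per-pairing
tournament has 20,000 observations and error df 19,995); pairwise
comparisons are two-sample t tests, pooled-variance by default with Welch
as an option, Bonferroni-adjusted over all k(k − 1)/2 pairs
(p·m capped at 1). If every team's goal differences are constant the
result is flagged degenerate rather than reporting an infinite F.
Internally, per-team game rows are canonically sorted before aggregation
so all statistics are exactly invariant to ledger row order.

## Synthetic sessions

The generator emulates the statistical skeleton of 20-min free play: per
session, `n_bouts` bouts; per bout, a step count from a discretized
truncated normal (max(1, round(𝒩(mean, sd)))), a per-bout turn bias from
𝒩(0, `turn_bias_sd_deg`), and a fresh uniform initial heading; per step,
heading increments by bias + 𝒩(0, `heading_sd_deg`) (a correlated random
walk, the standard movement-ecology model), step length truncated normal,
steps at a fixed 0.3 s cadence. Bouts are separated by pauses drawn from
a truncated normal with floor 0.6 s — safely above the 0.5 s stationary
threshold so segmentation recovers exactly the generated bout count. The
cadence sits below the threshold for the same reason; a 0.5 s cadence
would equal the threshold and dissolve every bout. Near a wall
(< 0.3 m) the heading snaps toward the room center, so no rejection
sampling is needed and every step is in-room by construction.

Knob → metric coupling is monotone (verified as a property): heading
noise drives direction variety, turn-bias dispersion drives shape
variety, step-count dispersion drives length variety. Two caveats locate
the limits of that coupling. First, wall avoidance injects large heading
changes, which puts a noise floor under the direction and shape metrics
for near-straight walkers in the small default room; the monotonicity
property tests therefore run in a 20 × 30 m arena where wall encounters
are rare. Second, the SE normalization couples every metric to the bout
count (above).

Two parameter families ship with the package. `PRESETS` (green, yellow,
blue, red, purple) encode five *qualitative* high/low combinations of the
four dimensions, including deliberately similar pairs; they are ordinal
patterns, not fits to any real cohort, and are not well separated by
construction. `separated_cohort_params()` is the design for
parameter-recovery experiments: distinct bout counts (≥ 50, so SE noise
is small and the zero-within-variance bout-count feature separates
groups), adjacent groups contrasting on at least two dimensions, and
bout-length SDs chosen on the SE scale (sd/√n_bouts) rather than the SD
scale. With this design the ground-truth partition is the within-cluster
sum-of-squares optimum and the full metrics → clustering pipeline
recovers it exactly (adjusted Rand index 1.0 across seeds in the test
suite).

What passing these tests shows — and does not. The pipeline is validated
on data whose generating process matches its assumptions (independent
bouts, stationary per-bout turning law, fixed cadence). Real free-play
walking has obstacle- and social-driven path structure, variable cadence,
drifting arousal, and digitization noise; recovery results here bound
what is attainable under clean conditions and say nothing about
robustness to those factors.

## Problem sizes

Defaults used throughout tests and examples: 60–200 bouts per synthetic
session, 75-walker cohorts (5 × 15), 10-seed recovery replicates,
5-point monotonicity grids with 200 bouts per setting and 3 seeds, and
100 random instances for the exhaustive-optimum clustering check. These
sizes give stable statistics at interactive runtimes.

## Known limitations

- The variety metrics' SE normalization makes them sample-size dependent
  (see above); comparing walkers with very different bout counts on the
  SE dimensions conflates dispersion with opportunity.
- The balanced assignment is exact but cubic; cohorts in the thousands
  would need the greedy or sliced assignment variants this package
  deliberately omits.
- Course building assumes a walker's consecutive bouts start roughly
  where the previous one ended (true of free play, enforced by the
  generator); sessions with teleporting coordinates would produce long
  implicit travel between waypoints.
- The walk-engine optimization and soccer simulation that consume these
  courses are external systems; this package ends at the course schedule
  and begins again at the match ledger.
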