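# varietywalk

Tools for asking whether *variety* in everyday walking is useful training
for functional locomotion. During free play, new walkers do not practice
steady straight-line gait: they walk in short bouts along curved,
multi-directional paths with frequent starts and stops. `varietywalk`
implements the computational pipeline for studying that variety with
simulated humanoid soccer as the test bed: it quantifies path variety per
walker, clusters walkers into equal-size groups by variety profile, turns
groups of walking sessions into walk-training courses for a robot walk
optimizer, and scores the resulting round-robin tournaments.

It is a library for researchers in developmental movement science and
robot-locomotion training; everything is driven from Python (see
`examples/`).

## The quantities at its core

A **session** is an ordered stream of digitized foot placements
(t, x, y) in a playroom (default 6 × 9 m, 20 min). A **bout** is a maximal
run of steps with no stationary gap ≥ 500 ms. Per session, four *variety*
dimensions are computed (dispersion, not mean level; SE = s/√n with sample
SD s):

- **shape variety** — SE of per-bout path curvature. For bouts of ≥ 4
  steps, curvature is the straightness index: the mean of (i) chord/arc of
  the whole bout and (ii) the mean chord/arc over every consecutive
  3-point window. 1 = perfectly straight; → 0 = maximally tortuous.
- **direction variety** — SE of the heading change |∠(vᵢ, vᵢ₊₁)| in
  degrees between consecutive step displacements, pooled across bouts.
- **length variety** — SE of the number of steps per bout.
- **starts and stops** — the total number of bouts.

Walkers are partitioned on these 4-D profiles by **equal-cardinality
k-means**: the assignment step is solved as a balanced transportation
problem (each of the k clusters has capacity n/k, cost = squared distance
to the centroid), alternated with centroid updates; every cluster holds
exactly n/k walkers at every iteration.

Groups of sessions become **training courses**: each session's walk/stop
timeline (stationary periods capped at 2 s) contributes one randomly
sampled 4-min contiguous block, and 15 blocks concatenate into a 1-h
schedule of walk-to-waypoint and timed-stop elements. Geometric baselines
(line, circle, square) are built to the same schedule format.

Tournaments are scored with the standard league system (3 points per win,
1 per tie, 0 per loss), per-team goal statistics (M ± SE), average goal
difference, pairwise win/goal matrices, and a one-way ANOVA on per-game
goal difference with Bonferroni pairwise comparisons.

Because no public step-placement data exist, a seeded **synthetic
generator** produces infant-like sessions as bouts of a correlated random
walk in a bounded room, with knobs that map onto the four variety
dimensions (see `docs/methods.md`).

## Worked example

```bash
python examples/analyze_session.py
```

```
session demo-walker: 786 steps, 60 bouts
median steps/bout: 14
shape variety     (SE of path curvature): 0.0135
direction variety (SE of heading change): 0.779 deg
length variety    (SE of steps per bout): 0.701 steps
starts and stops  (number of bouts):      60
```

A 20-min synthetic session with 786 steps splits into 60 bouts; the four
numbers are that walker's variety profile — the dispersion of its bout
curvatures, step-to-step heading changes, and bout lengths, plus how often
it started and stopped. `examples/cluster_cohort.py` clusters 75 such
walkers into five groups of exactly 15 (adjusted Rand index 1.0 against
the generating groups); `examples/build_courses.py` prints

```
infant-course    3600.0 s,  8706 walk targets, 710 stops (longest stop 2.0 s)
line-course        90.0 s,    10 walk targets,  10 stops (longest stop 2.0 s)
circle-course     154.0 s,   140 walk targets,   7 stops (longest stop 2.0 s)
square-course     350.0 s,    56 walk targets,  35 stops (longest stop 2.0 s)
```

— a 1-h infant-derived course (15 × 4 min, no stop above the 2 s cap)
next to the three geometric baselines. `examples/score_tournament.py`
re-scores the bundled tournament tables and runs the full league /
goal-difference analysis on a synthetic ledger.

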