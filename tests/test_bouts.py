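"""Bout segmentation, curvature, heading changes, and variety profiles."""

import math
import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from varietywalk.bouts import (
    WalkingBout,
    bout_curvature,
    heading_changes,
    segment_bouts,
    standard_error,
    variety_profile,
)
from varietywalk.io import Session, StepEvent

from conftest import make_session


def bout_of(points, dt=0.1):
    return WalkingBout([StepEvent(i * dt, x, y) for i, (x, y) in enumerate(points)])


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def test_single_bout_when_all_gaps_below_threshold():
    s = make_session([(1, 1), (1.2, 1), (1.4, 1)], times=[0, 0.4, 0.8])
    bouts = segment_bouts(s)
    assert len(bouts) == 1
    assert bouts[0].n_steps == 3


def test_gap_at_threshold_splits():
    s = make_session([(1, 1), (1.2, 1), (1.4, 1), (1.6, 1)], times=[0, 0.4, 1.0, 1.4])
    bouts = segment_bouts(s)
    assert [b.n_steps for b in bouts] == [2, 2]
    assert bouts[1].onset == 1.0
    # 0.6 - 0.1 = exactly-0.5 gap also splits (threshold is inclusive)
    s2 = make_session([(1, 1), (1.2, 1)], times=[0.1, 0.6])
    assert len(segment_bouts(s2)) == 2


def test_empty_session_gives_no_bouts():
    assert segment_bouts(Session("e", [])) == []


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(0.05, 1.5), min_size=0, max_size=60), st.integers(0, 2**31))
def test_segmentation_matches_brute_force(gaps, seed):
    """Random gap streams: partition equals an independent cut-index oracle."""
    rng = np.random.default_rng(seed)
    times = list(np.cumsum([0.0] + gaps)) if gaps else [0.0]
    pts = rng.uniform(0.5, 5.5, size=(len(times), 2))
    s = make_session([tuple(p) for p in pts], times=times)
    bouts = segment_bouts(s)
    # oracle: cut wherever the time difference reaches 0.5
    cuts = [0] + [i for i in range(1, len(times)) if times[i] - times[i - 1] >= 0.5]
    sizes = [b - a for a, b in zip(cuts, cuts[1:] + [len(times)])]
    assert [b.n_steps for b in bouts] == sizes
    assert sum(b.n_steps for b in bouts) == s.n_steps  # partition


def test_inserting_long_gap_adds_exactly_one_bout():
    times = [0.3 * i for i in range(10)]
    pts = [(1 + 0.1 * i, 2.0) for i in range(10)]
    base = make_session(pts, times=times)
    shifted = [t if i < 5 else t + 1.0 for i, t in enumerate(times)]
    split = make_session(pts, times=shifted)
    assert len(segment_bouts(split)) == len(segment_bouts(base)) + 1


# ---------------------------------------------------------------------------
# curvature
# ---------------------------------------------------------------------------


def test_collinear_bout_curvature_is_one():
    assert bout_curvature(bout_of([(0, 0), (1, 0), (2, 0), (3, 0)])) == 1.0


def test_square_corner_worked_example():
    # overall chord/arc = 1/3; both triples sqrt(2)/2; mean of the two parts
    val = bout_curvature(bout_of([(0, 0), (1, 0), (1, 1), (0, 1)]))
    assert val == pytest.approx((1 / 3 + math.sqrt(2) / 2) / 2, abs=1e-12)


def test_short_and_degenerate_bouts_undefined():
    assert bout_curvature(bout_of([(0, 0), (1, 0), (2, 0)])) is None
    assert bout_curvature(bout_of([(1, 1)] * 5)) is None


@settings(max_examples=50, deadline=None)
@given(st.integers(0, 2**31), st.integers(4, 12))
def test_curvature_bounds_and_rigid_motion_invariance(seed, n):
    rng = np.random.default_rng(seed)
    pts = np.cumsum(rng.normal(0, 0.2, size=(n, 2)), axis=0)
    b = bout_of([tuple(p) for p in pts])
    c = bout_curvature(b)
    if c is None:
        return
    assert 0 < c <= 1 + 1e-12
    theta = rng.uniform(0, 2 * math.pi)
    R = np.array([[math.cos(theta), -math.sin(theta)], [math.sin(theta), math.cos(theta)]])
    moved = pts @ R.T + rng.uniform(-3, 3, size=2)
    assert bout_curvature(bout_of([tuple(p) for p in moved])) == pytest.approx(c, abs=1e-9)
    hc = heading_changes(b)
    hc_moved = heading_changes(bout_of([tuple(p) for p in moved]))
    assert hc_moved == pytest.approx(hc, abs=1e-7)


# ---------------------------------------------------------------------------
# heading changes
# ---------------------------------------------------------------------------


def test_collinear_heading_changes_zero():
    assert heading_changes(bout_of([(0, 0), (1, 0), (2, 0), (3, 0)])) == [0.0, 0.0]


def test_right_angle_zigzag():
    assert heading_changes(bout_of([(0, 0), (1, 0), (1, 1), (2, 1)])) == pytest.approx(
        [90.0, 90.0]
    )


def test_reversal_is_180():
    assert heading_changes(bout_of([(0, 0), (1, 0), (0, 0)])) == pytest.approx([180.0])


def test_signed_heading_changes():
    left_turn = heading_changes(bout_of([(0, 0), (1, 0), (1, 1)]), signed=True)
    right_turn = heading_changes(bout_of([(0, 0), (1, 0), (1, -1)]), signed=True)
    assert left_turn == pytest.approx([90.0])
    assert right_turn == pytest.approx([-90.0])


def test_zero_length_displacement_pair_skipped():
    b = WalkingBout(
        [
            StepEvent(0.0, 0, 0),
            StepEvent(0.1, 1, 0),
            StepEvent(0.2, 1, 0),  # zero displacement
            StepEvent(0.3, 2, 0),
        ]
    )
    assert heading_changes(b) == []


# ---------------------------------------------------------------------------
# variety profiles
# ---------------------------------------------------------------------------


def test_identical_straight_bouts_zero_varieties():
    pts, times = [], []
    t = 0.0
    for b in range(3):
        for i in range(4):
            pts.append((1.0 + 0.3 * i, 2.0 + b))
            times.append(t)
            t += 0.3
        t += 1.0
    p = variety_profile(make_session(pts, times=times))
    assert p.shape_variety == 0.0
    assert p.direction_variety == 0.0
    assert p.length_variety == 0.0
    assert p.n_bouts == 3


def test_single_bout_flags_length_variety():
    p = variety_profile(make_session([(1, 1), (1.3, 1), (1.6, 1), (1.9, 1)]))
    assert p.length_variety is None
    assert "length_variety" in p.flags
    assert not p.is_complete
    with pytest.raises(ValueError):
        p.as_vector()


def test_standard_error_needs_two_values():
    assert standard_error([1.0]) is None
    assert standard_error([1.0, 2.0, 3.0]) == pytest.approx(1.0 / math.sqrt(3))


def test_profile_matches_spreadsheet_recomputation(rng):
    """Independent plain-Python recomputation agrees to 1e-9."""
    from varietywalk.synth import PathGenParams, generate_session

    s = generate_session(PathGenParams(n_bouts=25, seed=11), "oracle")
    p = variety_profile(s)

    # --- independent route: manual segmentation and statistics module ---
    groups, cur = [], [s.steps[0]]
    for a, b in zip(s.steps, s.steps[1:]):
        if b.t - a.t >= 0.5:
            groups.append(cur)
            cur = []
        cur.append(b)
    groups.append(cur)

    def se(vals):
        return statistics.stdev(vals) / math.sqrt(len(vals))

    curvs = []
    angles = []
    for g in groups:
        P = [(st_.x, st_.y) for st_ in g]
        if len(P) >= 4:
            arc = sum(math.dist(a, b) for a, b in zip(P, P[1:]))
            trip = [
                math.dist(P[i], P[i + 2])
                / (math.dist(P[i], P[i + 1]) + math.dist(P[i + 1], P[i + 2]))
                for i in range(len(P) - 2)
            ]
            curvs.append((math.dist(P[0], P[-1]) / arc + statistics.mean(trip)) / 2)
        for i in range(len(P) - 2):
            v1 = (P[i + 1][0] - P[i][0], P[i + 1][1] - P[i][1])
            v2 = (P[i + 2][0] - P[i + 1][0], P[i + 2][1] - P[i + 1][1])
            dot = v1[0] * v2[0] + v1[1] * v2[1]
            n1, n2 = math.hypot(*v1), math.hypot(*v2)
            if n1 and n2:
                angles.append(math.degrees(math.acos(max(-1, min(1, dot / (n1 * n2))))))

    assert len(groups) == p.n_bouts
    assert p.shape_variety == pytest.approx(se(curvs), abs=1e-9)
    assert p.direction_variety == pytest.approx(se(angles), abs=1e-9)
    assert p.length_variety == pytest.approx(se([len(g) for g in groups]), abs=1e-9)


def test_per_bout_direction_aggregation_option():
    s = make_session(
        [(0, 0), (1, 0), (1, 1), (2, 1), (2.5, 1)],
        times=[0, 0.3, 0.6, 0.9, 1.2],
    )
    pooled = variety_profile(s, pool_direction=True)
    assert pooled.direction_variety == pytest.approx(standard_error([90.0, 90.0, 0.0]))
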