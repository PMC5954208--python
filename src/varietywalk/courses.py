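"""Build walk-training courses for a walk-engine optimizer.

Two families of course:

* *Infant-derived*: each walker's session becomes an alternating walk/stop
  timeline (stationary periods capped at 2 s — a robot is fully stabilized
  after about 2 s, so longer pauses add nothing); a contiguous 4-min block
  of walking time plus stops is sampled at random from each of 15 timelines
  (a timeline shorter than 4 min is repeated end-to-start until the block
  fills); the 15 blocks are concatenated into a 1-h course.
* *Geometric baselines*: a straight line (10 segments of 7 s walking + 2 s
  stop), a fixed circle (heading updated every second for 20 s, then a 2 s
  stop, 7 repetitions), and a square (one lap stopping only at the end
  alternating with one lap stopping 2 s at every corner; 5 s of walking per
  side, 20 s per lap; 7 repetitions of the alternating pair).

Room coordinates are mapped onto the field by translating the room center
to the field center, meters preserved 1:1. Geometric course sizes derive
from the course's nominal walk speed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bouts import segment_bouts
from .io import CourseElement, Session, TrainingCourse

__all__ = [
    "CourseRecipe",
    "WalkSegment",
    "StopSegment",
    "session_to_timeline",
    "sample_block",
    "build_infant_course",
    "line_course",
    "circle_course",
    "square_course",
]

DEFAULT_WALK_SPEED = 0.4  # m/s, conservative humanoid walking pace


@dataclass
class CourseRecipe:
    """Parameters of the infant-derived course construction.

    Defaults give 15 sessions x 240 s = one 3600 s (1 h) course with
    stationary periods capped at 2 s.
    """

    stop_cap: float = 2.0
    block_duration: float = 240.0
    total_sessions: int = 15
    seed: int = 0
    grid_cell: float = 1.0  # field grid resolution, meters (1:1 mapping)

    def nominal_course_duration(self) -> float:
        return self.block_duration * self.total_sessions


@dataclass
class WalkSegment:
    """A run of timed waypoints in field coordinates; times are relative to
    segment start with the first waypoint at t = 0."""

    waypoints: list[tuple[float, float, float]]  # (t_rel, x, y)

    @property
    def duration(self) -> float:
        return self.waypoints[-1][0]


@dataclass
class StopSegment:
    duration: float


Timeline = list  # of WalkSegment | StopSegment, strictly alternating


def room_to_field(
    x: float, y: float, room_width: float, room_length: float
) -> tuple[float, float]:
    """Translate room-frame meters to field-frame meters (centers aligned)."""
    return (x - room_width / 2.0, y - room_length / 2.0)


def session_to_timeline(session: Session, stop_cap: float = 2.0) -> Timeline:
    """Convert a session into an alternating walk/stop timeline.

    Walk segments carry the per-step waypoints of each bout mapped into
    field coordinates; the stationary period between consecutive bouts
    becomes a stop of ``min(actual pause, stop_cap)`` seconds. Walk time is
    preserved exactly.
    """
    if stop_cap <= 0:
        raise ValueError("stop_cap must be positive")
    bouts = segment_bouts(session)
    timeline: Timeline = []
    for i, bout in enumerate(bouts):
        if i > 0:
            pause = bout.onset - bouts[i - 1].offset
            timeline.append(StopSegment(min(pause, stop_cap)))
        onset = bout.onset
        wps = [
            (s.t - onset, *room_to_field(s.x, s.y, session.room_width, session.room_length))
            for s in bout.steps
        ]
        timeline.append(WalkSegment(wps))
    return timeline


# ---------------------------------------------------------------------------
# Block sampling
# ---------------------------------------------------------------------------

@dataclass
class _Piece:
    """Flattened element precursor: one inter-waypoint walk leg or one stop."""

    mode: str  # walk | stop
    duration: float
    start: tuple[float, float] | None = None
    end: tuple[float, float] | None = None

    def position_at(self, tau: float) -> tuple[float, float]:
        if self.duration <= 0:
            return self.end
        f = tau / self.duration
        return (
            self.start[0] + f * (self.end[0] - self.start[0]),
            self.start[1] + f * (self.end[1] - self.start[1]),
        )


def _flatten(timeline: Timeline) -> list[_Piece]:
    pieces: list[_Piece] = []
    for seg in timeline:
        if isinstance(seg, StopSegment):
            pieces.append(_Piece("stop", seg.duration))
        else:
            t0, x0, y0 = seg.waypoints[0]
            # first waypoint is a zero-duration leg marking the bout's start
            pieces.append(_Piece("walk", 0.0, (x0, y0), (x0, y0)))
            prev_t, prev_p = t0, (x0, y0)
            for t, x, y in seg.waypoints[1:]:
                pieces.append(_Piece("walk", t - prev_t, prev_p, (x, y)))
                prev_t, prev_p = t, (x, y)
    return pieces


def sample_block(
    timeline: Timeline,
    block_duration: float = 240.0,
    seed: int | np.random.Generator = 0,
) -> list[CourseElement]:
    """Sample one contiguous block of exactly ``block_duration`` seconds.

    The start is drawn uniformly over feasible starts; a start that falls
    inside a stop advances to the next walking content, so blocks always
    open with walking. A timeline shorter than the block is traversed
    end-to-start (cyclically) until the duration accumulates. Elements cut
    by a block boundary are split at the position interpolated along the
    walk leg, so the block duration is exact.
    """
    pieces = _flatten(timeline)
    if not pieces:
        raise ValueError("timeline is empty")
    durations = np.array([p.duration for p in pieces])
    total = float(durations.sum())
    walk_time = float(sum(p.duration for p in pieces if p.mode == "walk"))
    if walk_time <= 0:
        raise ValueError("timeline has no walking time to sample")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    if total > block_duration:
        start = float(rng.uniform(0.0, total - block_duration))
    else:
        start = float(rng.uniform(0.0, total))

    # locate the piece containing `start` and skip out of stop content
    bounds = np.concatenate([[0.0], np.cumsum(durations)])
    idx = int(np.searchsorted(bounds, start, side="right") - 1)
    idx = min(idx, len(pieces) - 1)
    offset = start - bounds[idx]
    while pieces[idx].mode == "stop":
        idx = (idx + 1) % len(pieces)
        offset = 0.0

    elements: list[CourseElement] = []
    remaining = block_duration
    guard = 0
    while remaining > 0:
        p = pieces[idx]
        avail = p.duration - offset
        if p.mode == "walk":
            if p.duration == 0.0:
                if offset == 0.0:
                    elements.append(CourseElement("walk", p.end, 0.0))
            elif avail > 0:
                take = min(avail, remaining)
                cut = offset + take
                target = p.end if cut >= p.duration else p.position_at(cut)
                elements.append(CourseElement("walk", target, take))
                remaining -= take
        else:
            take = min(avail, remaining)
            if take > 0:
                elements.append(CourseElement("stop", None, take))
                remaining -= take
        idx = (idx + 1) % len(pieces)
        offset = 0.0
        guard += 1
        if guard > 10 * len(pieces) * (1 + int(block_duration // max(walk_time, 1e-9))):
            raise RuntimeError("block sampling failed to accumulate duration")
    return elements


def build_infant_course(
    sessions: Sequence[Session],
    recipe: CourseRecipe | None = None,
    course_id: str = "infant-course",
) -> TrainingCourse:
    """Concatenate one randomly sampled block per session into one course.

    Requires exactly ``recipe.total_sessions`` sessions (default 15); the
    result lasts ``total_sessions x block_duration`` seconds (3600 s at
    defaults). Deterministic given the recipe seed.
    """
    recipe = recipe or CourseRecipe()
    if len(sessions) != recipe.total_sessions:
        raise ValueError(
            f"need exactly {recipe.total_sessions} sessions, got {len(sessions)}"
        )
    master = np.random.default_rng(recipe.seed)
    elements: list[CourseElement] = []
    for session in sessions:
        child = np.random.default_rng(int(master.integers(2**31)))
        timeline = session_to_timeline(session, recipe.stop_cap)
        elements.extend(sample_block(timeline, recipe.block_duration, child))
    return TrainingCourse(course_id, elements, nominal_walk_speed=DEFAULT_WALK_SPEED)


# ---------------------------------------------------------------------------
# Geometric baseline courses
# ---------------------------------------------------------------------------

def line_course(
    n_segments: int = 10,
    walk_time: float = 7.0,
    stop_time: float = 2.0,
    nominal_walk_speed: float = DEFAULT_WALK_SPEED,
    start: tuple[float, float] = (-14.0, 0.0),
) -> TrainingCourse:
    """Straight-line course: walk continually forward for ``n_segments``
    segments of ``walk_time`` s each, stopping ``stop_time`` s after each."""
    elements: list[CourseElement] = []
    x, y = start
    for i in range(1, n_segments + 1):
        elements.append(
            CourseElement("walk", (x + i * nominal_walk_speed * walk_time, y), walk_time)
        )
        elements.append(CourseElement("stop", None, stop_time))
    return TrainingCourse("line-course", elements, nominal_walk_speed)


def circle_course(
    radius: float = 1.5,
    n_repeats: int = 7,
    n_updates: int = 20,
    update_interval: float = 1.0,
    stop_time: float = 2.0,
    nominal_walk_speed: float = DEFAULT_WALK_SPEED,
    center: tuple[float, float] = (0.0, 0.0),
) -> TrainingCourse:
    """Fixed-circle course: the target heading is updated every
    ``update_interval`` s for ``n_updates`` updates, then a stop; repeated
    ``n_repeats`` times, continuing around the same circle."""
    if radius <= 0:
        raise ValueError("radius must be positive")
    dtheta = nominal_walk_speed * update_interval / radius
    elements: list[CourseElement] = []
    theta = 0.0
    for _ in range(n_repeats):
        for _ in range(n_updates):
            theta += dtheta
            elements.append(
                CourseElement(
                    "walk",
                    (
                        center[0] + radius * math.cos(theta),
                        center[1] + radius * math.sin(theta),
                    ),
                    update_interval,
                )
            )
        elements.append(CourseElement("stop", None, stop_time))
    return TrainingCourse("circle-course", elements, nominal_walk_speed)


def square_course(
    side_duration: float = 5.0,
    stop_time: float = 2.0,
    n_repeats: int = 7,
    nominal_walk_speed: float = DEFAULT_WALK_SPEED,
    center: tuple[float, float] = (0.0, 0.0),
) -> TrainingCourse:
    """Square course alternating lap styles.

    Each repetition is one lap stopping only at the end followed by one lap
    stopping at every corner; each lap is 4 sides of ``side_duration`` s of
    walking (20 s of walking per lap at defaults). Side length derives from
    the nominal walk speed.
    """
    half = nominal_walk_speed * side_duration / 2.0
    corners = [
        (center[0] - half, center[1] - half),
        (center[0] + half, center[1] - half),
        (center[0] + half, center[1] + half),
        (center[0] - half, center[1] + half),
    ]
    elements: list[CourseElement] = []
    for _ in range(n_repeats):
        # lap 1: around the square, stop once at the end
        for c in corners[1:] + corners[:1]:
            elements.append(CourseElement("walk", c, side_duration))
        elements.append(CourseElement("stop", None, stop_time))
        # lap 2: around the square, stop at every corner
        for c in corners[1:] + corners[:1]:
            elements.append(CourseElement("walk", c, side_duration))
            elements.append(CourseElement("stop", None, stop_time))
    return TrainingCourse("square-course", elements, nominal_walk_speed)
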