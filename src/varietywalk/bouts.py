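"""Walking-bout segmentation and the four per-session variety dimensions.

A *bout* is a maximal run of steps uninterrupted by a stationary period of
at least 500 ms. Per session we quantify *variety* — dispersion, not mean
level — along four interdependent dimensions:

* shape variety: standard error (SE) of per-bout path curvature, where
  curvature is the straightness index chord/arc, averaged between the whole
  bout and its overlapping step triples; only bouts of >= 4 steps contribute;
* direction variety: SE of the heading change (degrees) between each pair of
  consecutive step displacements, pooled across bouts;
* length variety: SE of the number of steps per bout;
* number of starts and stops: the total bout count.

SE is sample SD (n-1 denominator) divided by sqrt(n). A dimension with
fewer than two contributing values is *undefined* and flagged explicitly —
never silently zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import Session, StepEvent

__all__ = [
    "STATIONARY_THRESHOLD",
    "MIN_STEPS_FOR_CURVATURE",
    "WalkingBout",
    "VarietyProfile",
    "segment_bouts",
    "bout_curvature",
    "heading_changes",
    "variety_profile",
    "standard_error",
]

#: A stationary gap of at least this many seconds ends a walking bout.
STATIONARY_THRESHOLD = 0.5

#: Path curvature is only defined for bouts with at least this many steps.
MIN_STEPS_FOR_CURVATURE = 4


@dataclass
class WalkingBout:
    """A maximal run of steps with every inter-step gap below the stationary
    threshold."""

    steps: list[StepEvent]

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValueError("a bout contains at least one step")

    @property
    def n_steps(self) -> int:
        return len(self.steps)

    @property
    def onset(self) -> float:
        return self.steps[0].t

    @property
    def offset(self) -> float:
        return self.steps[-1].t

    @property
    def path_length(self) -> float:
        """Total distance traveled step to step (the arc length)."""
        pts = self._points()
        return float(np.sum(np.hypot(np.diff(pts[:, 0]), np.diff(pts[:, 1]))))

    @property
    def displacement(self) -> float:
        """Straight-line chord from first to last step."""
        p0, p1 = self.steps[0], self.steps[-1]
        return math.hypot(p1.x - p0.x, p1.y - p0.y)

    def _points(self) -> np.ndarray:
        return np.array([[s.x, s.y] for s in self.steps], dtype=float)


def segment_bouts(
    session: Session, stationary_threshold: float = STATIONARY_THRESHOLD
) -> list[WalkingBout]:
    """Partition a session's steps into walking bouts.

    A new bout starts whenever the gap to the previous step is at least
    ``stationary_threshold`` seconds. Every step lands in exactly one bout;
    an empty session yields an empty list.
    """
    if stationary_threshold <= 0:
        raise ValueError("stationary_threshold must be positive")
    bouts: list[WalkingBout] = []
    current: list[StepEvent] = []
    for step in session.steps:
        if current and step.t - current[-1].t >= stationary_threshold:
            bouts.append(WalkingBout(current))
            current = []
        current.append(step)
    if current:
        bouts.append(WalkingBout(current))
    return bouts


def bout_curvature(
    bout: WalkingBout, min_steps: int = MIN_STEPS_FOR_CURVATURE
) -> float | None:
    """Path curvature (straightness index) of one bout, or None if undefined.

    For bouts of >= ``min_steps`` steps the overall curvature is the chord
    (shortest distance start to end) divided by the arc (total distance
    traveled); the step-to-step curvature is the same ratio over every
    overlapping run of 3 consecutive steps; the result is the unweighted
    mean of the overall value and the mean triple value. 1 means perfectly
    straight, values near 0 a maximally tortuous path.

    Undefined (None) when the bout is too short, when the whole path has
    zero arc length (all steps coincident), or when no step triple has a
    positive arc.
    """
    if bout.n_steps < min_steps:
        return None
    pts = bout._points()
    arc = bout.path_length
    if arc <= 0.0:
        return None
    overall = bout.displacement / arc
    triple_vals: list[float] = []
    for i in range(bout.n_steps - 2):
        a, b, c = pts[i], pts[i + 1], pts[i + 2]
        seg = math.dist(a, b) + math.dist(b, c)
        if seg > 0.0:
            triple_vals.append(math.dist(a, c) / seg)
    if not triple_vals:
        return None
    return 0.5 * (overall + float(np.mean(triple_vals)))


def heading_changes(bout: WalkingBout, *, signed: bool = False) -> list[float]:
    """Heading change, in degrees, between each pair of consecutive step
    displacements.

    For displacement vectors ``v_i = p_{i+1} - p_i`` this is the plane angle
    between ``v_i`` and ``v_{i+1}``: absolute magnitude in [0, 180] by
    default, or the signed angle in (-180, 180] with ``signed=True``
    (positive = counterclockwise). Pairs involving a zero-length
    displacement are skipped. Bouts of fewer than 3 steps yield no pairs.
    """
    pts = bout._points()
    vecs = np.diff(pts, axis=0)
    out: list[float] = []
    for v1, v2 in zip(vecs[:-1], vecs[1:]):
        if np.hypot(*v1) == 0.0 or np.hypot(*v2) == 0.0:
            continue
        ang = math.degrees(
            math.atan2(v1[0] * v2[1] - v1[1] * v2[0], v1[0] * v2[0] + v1[1] * v2[1])
        )
        if ang <= -180.0:  # atan2 edge: map -180 to +180
            ang = 180.0
        out.append(ang if signed else abs(ang))
    return out


def standard_error(values: Sequence[float]) -> float | None:
    """Sample-SD-based standard error, or None for fewer than 2 values."""
    n = len(values)
    if n < 2:
        return None
    return float(np.std(values, ddof=1) / math.sqrt(n))


@dataclass
class VarietyProfile:
    """The four-dimensional variety summary of one walker's session.

    Undefined dimensions are None with the reason recorded in ``flags``.
    """

    session_id: str
    shape_variety: float | None
    direction_variety: float | None
    length_variety: float | None
    n_bouts: int
    flags: dict[str, str] = field(default_factory=dict)

    FEATURES = ("shape_variety", "direction_variety", "length_variety", "n_bouts")

    @property
    def is_complete(self) -> bool:
        return not self.flags

    def as_vector(self) -> list[float]:
        if not self.is_complete:
            raise ValueError(
                f"profile {self.session_id!r} has undefined dimensions: "
                f"{sorted(self.flags)}"
            )
        return [
            self.shape_variety,
            self.direction_variety,
            self.length_variety,
            float(self.n_bouts),
        ]


def variety_profile(
    session: Session,
    *,
    stationary_threshold: float = STATIONARY_THRESHOLD,
    min_steps_curvature: int = MIN_STEPS_FOR_CURVATURE,
    pool_direction: bool = True,
) -> VarietyProfile:
    """Compute the four variety dimensions for one session.

    ``pool_direction=True`` (default) takes the SE over the heading changes
    of all step pairs pooled across bouts; ``False`` takes the SE over
    per-bout mean heading changes instead.
    """
    bouts = segment_bouts(session, stationary_threshold)
    flags: dict[str, str] = {}

    curvatures = [
        c for c in (bout_curvature(b, min_steps_curvature) for b in bouts) if c is not None
    ]
    shape = standard_error(curvatures)
    if shape is None:
        flags["shape_variety"] = (
            f"needs >= 2 bouts of >= {min_steps_curvature} steps, have {len(curvatures)}"
        )

    if pool_direction:
        angles = [a for b in bouts for a in heading_changes(b)]
    else:
        per_bout = [heading_changes(b) for b in bouts]
        angles = [float(np.mean(a)) for a in per_bout if a]
    direction = standard_error(angles)
    if direction is None:
        flags["direction_variety"] = f"needs >= 2 heading changes, have {len(angles)}"

    lengths = [b.n_steps for b in bouts]
    length = standard_error(lengths)
    if length is None:
        flags["length_variety"] = f"needs >= 2 bouts, have {len(bouts)}"

    return VarietyProfile(
        session_id=session.session_id,
        shape_variety=shape,
        direction_variety=direction,
        length_variety=length,
        n_bouts=len(bouts),
        flags=flags,
    )
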