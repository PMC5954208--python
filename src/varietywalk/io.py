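"""Data model and readers/writers for step-event sessions, training courses,
and match ledgers.

Coordinate conventions
----------------------
Room frame: origin at one corner of the playroom, x across the short wall
(default 6 m), y along the long wall (default 9 m). Field frame: origin at
the center of the simulated soccer field (30 x 20 m), so x in [-15, 15] and
y in [-10, 10]. Time is in seconds, zero at session start, and step
timestamps are strictly increasing: two feet never land at the identical
instant in digitized data, so a tie is treated as a validation error.

File formats
------------
* Step tables: CSV with columns ``t,x,y[,foot]`` (canonical dialect writes
  all four columns, floats in shortest round-trip form).
* Match ledgers: CSV with columns ``team_a,team_b,goals_a,goals_b``.
* Training courses: JSON, one element per record, ``schema_version`` 1.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "FormatError",
    "ValidationError",
    "StepEvent",
    "Session",
    "CourseElement",
    "TrainingCourse",
    "MatchResult",
    "FIELD_LENGTH",
    "FIELD_WIDTH",
    "COURSE_SCHEMA_VERSION",
    "read_session",
    "write_session",
    "read_course",
    "write_course",
    "read_ledger",
    "write_ledger",
]

#: Simulated soccer field extent in meters (field frame is centered).
FIELD_LENGTH = 30.0
FIELD_WIDTH = 20.0

COURSE_SCHEMA_VERSION = 1

_FOOT_TAGS = ("left", "right", "unknown")


class FormatError(ValueError):
    """A file does not have the expected columns/structure."""


class ValidationError(ValueError):
    """A record violates a domain invariant (with row context where known)."""


@dataclass(frozen=True)
class StepEvent:
    """A single digitized foot placement.

    Parameters
    ----------
    t : float
        Seconds since session start, >= 0.
    x, y : float
        Room-frame coordinates in meters.
    foot : str
        ``left``, ``right`` or ``unknown``.
    """

    t: float
    x: float
    y: float
    foot: str = "unknown"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValidationError(f"non-finite step coordinates ({self.x}, {self.y})")
        if not math.isfinite(self.t) or self.t < 0:
            raise ValidationError(f"step timestamp must be finite and >= 0, got {self.t}")
        if self.foot not in _FOOT_TAGS:
            raise ValidationError(f"foot tag must be one of {_FOOT_TAGS}, got {self.foot!r}")

    @property
    def xy(self) -> tuple[float, float]:
        return (self.x, self.y)


@dataclass
class Session:
    """An ordered stream of step events recorded in a bounded playroom.

    Default geometry is a 6 x 9 m playroom observed for a 20-min (1200 s)
    free-play session. Steps must be strictly increasing in time and lie
    inside the room.
    """

    session_id: str
    steps: list[StepEvent] = field(default_factory=list)
    room_width: float = 6.0
    room_length: float = 9.0
    duration: float = 1200.0
    age_months: float | None = None
    walk_experience_months: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.room_width <= 0 or self.room_length <= 0:
            raise ValidationError("room dimensions must be positive")
        prev_t = -math.inf
        for i, s in enumerate(self.steps):
            if s.t <= prev_t:
                raise ValidationError(
                    f"step timestamps must be strictly increasing; row {i + 1} "
                    f"has t={s.t} after t={prev_t}"
                )
            prev_t = s.t
            if not (0.0 <= s.x <= self.room_width and 0.0 <= s.y <= self.room_length):
                raise ValidationError(
                    f"step {i + 1} at ({s.x}, {s.y}) outside room "
                    f"[0, {self.room_width}] x [0, {self.room_length}]"
                )

    @property
    def n_steps(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class CourseElement:
    """One schedule element of a training course.

    ``walk`` elements carry a field-frame target and the scheduled time
    budget (seconds) to reach it; ``stop`` elements carry only a duration.
    Walk durations come from the walker's own step timestamps for
    infant-derived courses, or from the heading-update interval for the
    geometric courses.
    """

    mode: str  # "walk" | "stop"
    target: tuple[float, float] | None = None
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.mode == "walk":
            if self.target is None:
                raise ValidationError("walk element requires a target")
            tx, ty = self.target
            if not (math.isfinite(tx) and math.isfinite(ty)):
                raise ValidationError("walk target must be finite")
            if abs(tx) > FIELD_LENGTH / 2 or abs(ty) > FIELD_WIDTH / 2:
                raise ValidationError(
                    f"walk target ({tx}, {ty}) outside field bounds "
                    f"[{-FIELD_LENGTH / 2}, {FIELD_LENGTH / 2}] x "
                    f"[{-FIELD_WIDTH / 2}, {FIELD_WIDTH / 2}]"
                )
            if not math.isfinite(self.duration) or self.duration < 0:
                raise ValidationError("walk duration must be finite and >= 0")
        elif self.mode == "stop":
            if self.target is not None:
                raise ValidationError("stop element takes no target")
            if not math.isfinite(self.duration) or self.duration <= 0:
                raise ValidationError("stop duration must be finite and > 0")
        else:
            raise ValidationError(f"element mode must be walk|stop, got {self.mode!r}")


@dataclass
class TrainingCourse:
    """An ordered walk/stop schedule handed to a walk-engine optimizer.

    Consecutive stop elements are merged on construction (durations summed),
    so a valid course alternates stops between walking content.
    ``nominal_walk_speed`` (m/s) is used to size the geometric courses.
    """

    course_id: str
    elements: list[CourseElement] = field(default_factory=list)
    nominal_walk_speed: float = 0.4

    def __post_init__(self) -> None:
        if self.nominal_walk_speed <= 0:
            raise ValidationError("nominal_walk_speed must be positive")
        self.elements = _merge_consecutive_stops(self.elements)

    def total_duration(self) -> float:
        return float(sum(e.duration for e in self.elements))

    def max_stop(self) -> float:
        stops = [e.duration for e in self.elements if e.mode == "stop"]
        return max(stops) if stops else 0.0

    def walk_elements(self) -> list[CourseElement]:
        return [e for e in self.elements if e.mode == "walk"]

    def stop_elements(self) -> list[CourseElement]:
        return [e for e in self.elements if e.mode == "stop"]


def _merge_consecutive_stops(elements: Sequence[CourseElement]) -> list[CourseElement]:
    merged: list[CourseElement] = []
    for el in elements:
        if merged and el.mode == "stop" and merged[-1].mode == "stop":
            merged[-1] = CourseElement("stop", None, merged[-1].duration + el.duration)
        else:
            merged.append(el)
    return merged


@dataclass(frozen=True)
class MatchResult:
    """One head-to-head game: the two team names and their goal counts."""

    team_a: str
    team_b: str
    goals_a: int
    goals_b: int

    def __post_init__(self) -> None:
        if self.team_a == self.team_b:
            raise ValidationError(f"a team cannot play itself ({self.team_a!r})")
        for g in (self.goals_a, self.goals_b):
            if not isinstance(g, int) or isinstance(g, bool) or g < 0:
                raise ValidationError(f"goals must be non-negative integers, got {g!r}")


# ---------------------------------------------------------------------------
# Step tables
# ---------------------------------------------------------------------------

def read_session(
    path: str | Path,
    session_id: str | None = None,
    *,
    room_width: float = 6.0,
    room_length: float = 9.0,
    duration: float = 1200.0,
    out_of_room: str = "error",
) -> Session:
    """Read a CSV step table (columns ``t,x,y[,foot]``) into a Session.

    ``out_of_room`` selects the policy for points outside the room:
    ``"error"`` (default) raises; ``"clamp"`` snaps them to the nearest wall,
    for noisy digitizations.
    """
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file, expected header t,x,y[,foot]")
        missing = {"t", "x", "y"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        rows = list(reader)

    steps: list[StepEvent] = []
    bad_rows: list[int] = []
    prev_t = -math.inf
    for i, row in enumerate(rows):
        try:
            t, x, y = float(row["t"]), float(row["x"]), float(row["y"])
        except (TypeError, ValueError) as exc:
            raise FormatError(f"{path}: non-numeric value in data row {i + 1}") from exc
        if t <= prev_t:
            bad_rows.append(i + 1)
        prev_t = t
        if out_of_room == "clamp":
            x = min(max(x, 0.0), room_width)
            y = min(max(y, 0.0), room_length)
        foot = (row.get("foot") or "unknown").strip() or "unknown"
        steps.append(StepEvent(t=t, x=x, y=y, foot=foot))
    if bad_rows:
        raise ValidationError(
            f"{path}: timestamps not strictly increasing at data row(s) {bad_rows}"
        )
    return Session(
        session_id=session_id if session_id is not None else path.stem,
        steps=steps,
        room_width=room_width,
        room_length=room_length,
        duration=duration,
    )


def _fmt(v: float) -> str:
    # shortest round-trip decimal form; keeps write(read(f)) byte-identical
    return repr(float(v))


def write_session(session: Session, path: str | Path) -> None:
    """Write a Session as a canonical CSV step table (``t,x,y,foot``)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write("t,x,y,foot\n")
        for s in session.steps:
            fh.write(f"{_fmt(s.t)},{_fmt(s.x)},{_fmt(s.y)},{s.foot}\n")


# ---------------------------------------------------------------------------
# Training courses (JSON schedule)
# ---------------------------------------------------------------------------

def write_course(course: TrainingCourse, path: str | Path) -> None:
    """Serialize a TrainingCourse to a JSON schedule (schema version 1)."""
    payload = {
        "schema_version": COURSE_SCHEMA_VERSION,
        "course_id": course.course_id,
        "nominal_walk_speed": course.nominal_walk_speed,
        "elements": [
            {"mode": e.mode, "duration": e.duration}
            if e.mode == "stop"
            else {"mode": e.mode, "target": list(e.target), "duration": e.duration}
            for e in course.elements
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1) + "\n")


def read_course(path: str | Path) -> TrainingCourse:
    """Read a JSON course schedule written by :func:`write_course`."""
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not valid JSON") from exc
    if not isinstance(payload, dict) or "elements" not in payload:
        raise FormatError(f"{path}: missing 'elements'")
    if payload.get("schema_version") != COURSE_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: unsupported schema_version {payload.get('schema_version')!r}"
        )
    elements = [
        CourseElement(
            mode=rec["mode"],
            target=tuple(rec["target"]) if rec.get("target") is not None else None,
            duration=float(rec["duration"]),
        )
        for rec in payload["elements"]
    ]
    return TrainingCourse(
        course_id=str(payload.get("course_id", path.stem)),
        elements=elements,
        nominal_walk_speed=float(payload.get("nominal_walk_speed", 0.4)),
    )


# ---------------------------------------------------------------------------
# Match ledgers
# ---------------------------------------------------------------------------

def read_ledger(path: str | Path) -> list[MatchResult]:
    """Read a CSV match ledger (``team_a,team_b,goals_a,goals_b``)."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty file")
        missing = {"team_a", "team_b", "goals_a", "goals_b"} - set(reader.fieldnames)
        if missing:
            raise FormatError(f"{path}: missing required columns {sorted(missing)}")
        results = []
        for i, row in enumerate(reader):
            try:
                ga, gb = int(row["goals_a"]), int(row["goals_b"])
            except (TypeError, ValueError) as exc:
                raise ValidationError(
                    f"{path}: non-integer goals in data row {i + 1}"
                ) from exc
            try:
                results.append(MatchResult(row["team_a"], row["team_b"], ga, gb))
            except ValidationError as exc:
                raise ValidationError(f"{path}: data row {i + 1}: {exc}") from exc
    return results


def write_ledger(results: Iterable[MatchResult], path: str | Path) -> None:
    """Write match results as a canonical CSV ledger."""
    with Path(path).open("w", newline="") as fh:
        fh.write("team_a,team_b,goals_a,goals_b\n")
        for r in results:
            fh.write(f"{r.team_a},{r.team_b},{r.goals_a},{r.goals_b}\n")
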