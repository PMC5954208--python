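"""Synthetic free-play walking sessions with controllable variety structure.

The generator emulates the statistical skeleton of 20-min infant free play
in a 6 x 9 m playroom: walking comes in bouts separated by stationary
pauses; within a bout the walker is a correlated random walk — each step
turns by a per-bout bias (``turn_bias``) plus symmetric Gaussian heading
noise — with steps at a fixed cadence and wall avoidance that steers toward
the room center near a wall. The knobs map onto the four variety
dimensions:

* ``heading_sd_deg`` (per-step heading-change SD)  -> direction variety;
* ``turn_bias_sd_deg`` (dispersion of the per-bout mean turn) -> shape
  variety (bouts range from straight to tightly curving);
* ``steps_per_bout_sd`` -> length variety;
* ``n_bouts`` -> the number of starts and stops.

Five named presets encode, qualitatively, five contrasting combinations of
high/low variety (see :data:`PRESETS`); they are ordinal patterns, not fits
to any real cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .io import Session, StepEvent

__all__ = [
    "PathGenParams",
    "generate_session",
    "generate_cohort",
    "PRESETS",
    "separated_cohort_params",
]


@dataclass
class PathGenParams:
    """Parameters of the synthetic session generator.

    Defaults approximate a 20-min free-play session: 60 bouts of ~12 steps
    at 0.3 s cadence (~720 steps, in line with the ~2,400 steps/h of
    free-play toddler locomotion) with 2.5 s pauses between bouts.
    """

    n_bouts: int = 60
    steps_per_bout_mean: float = 12.0
    steps_per_bout_sd: float = 6.0
    step_length_mean: float = 0.15  # meters
    step_length_sd: float = 0.04
    heading_sd_deg: float = 20.0  # per-step heading-change SD
    turn_bias_sd_deg: float = 8.0  # dispersion of per-bout mean turn
    pause_mean: float = 2.5  # seconds between bouts
    pause_sd: float = 1.5
    min_pause: float = 0.6  # kept above the 0.5 s stationary threshold
    step_interval: float = 0.3  # seconds per step (~3 steps/s)
    room_width: float = 6.0
    room_length: float = 9.0
    wall_margin: float = 0.3  # steer toward room center inside this band
    seed: int = 0

    def validate(self) -> None:
        room_min = min(self.room_width, self.room_length)
        if self.step_length_mean <= 0 or self.step_length_mean >= room_min:
            raise ValueError("step length must be positive and smaller than the room")
        for name in ("steps_per_bout_sd", "step_length_sd", "heading_sd_deg",
                     "turn_bias_sd_deg", "pause_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_bouts < 1:
            raise ValueError("n_bouts must be >= 1")
        if self.min_pause <= 0.5:
            raise ValueError("min_pause must exceed the 0.5 s stationary threshold")
        if not 0 < self.step_interval < 0.5:
            raise ValueError("step_interval must be in (0, 0.5) s")
        if 2 * self.wall_margin >= room_min:
            raise ValueError("wall_margin too large for the room")


def _draw_n_steps(params: PathGenParams, rng: np.random.Generator) -> int:
    # discretized truncated normal: at least one step per bout
    return max(1, int(round(rng.normal(params.steps_per_bout_mean,
                                       params.steps_per_bout_sd))))


def generate_session(
    params: PathGenParams | None = None, session_id: str = "synthetic"
) -> Session:
    """Generate one session; deterministic given ``params.seed``.

    Each bout draws a step count and a per-bout turn bias, starts from the
    previous bout's end position with a fresh uniform heading, and steps at
    the fixed cadence. Within 'wall_margin' of a wall the heading snaps
    toward the room center, so every step stays in the room.
    """
    params = params or PathGenParams()
    params.validate()
    rng = np.random.default_rng(params.seed)
    w, l = params.room_width, params.room_length
    cx, cy = w / 2.0, l / 2.0

    pos = np.array([
        rng.uniform(params.wall_margin + 0.2, w - params.wall_margin - 0.2),
        rng.uniform(params.wall_margin + 0.2, l - params.wall_margin - 0.2),
    ])
    t = 0.0
    steps: list[StepEvent] = []
    feet = ("left", "right")
    step_idx = 0
    for b in range(params.n_bouts):
        if b > 0:
            pause = max(params.min_pause,
                        rng.normal(params.pause_mean, params.pause_sd))
            t += pause
        n = _draw_n_steps(params, rng)
        bias = rng.normal(0.0, params.turn_bias_sd_deg)
        heading = rng.uniform(-math.pi, math.pi)
        for i in range(n):
            if i > 0:
                heading += math.radians(bias + rng.normal(0.0, params.heading_sd_deg))
                t += params.step_interval
            length = max(0.01, rng.normal(params.step_length_mean,
                                          params.step_length_sd))
            nxt = pos + length * np.array([math.cos(heading), math.sin(heading)])
            near_wall = (
                nxt[0] < params.wall_margin or nxt[0] > w - params.wall_margin
                or nxt[1] < params.wall_margin or nxt[1] > l - params.wall_margin
            )
            if near_wall:
                heading = math.atan2(cy - pos[1], cx - pos[0])
                nxt = pos + length * np.array([math.cos(heading), math.sin(heading)])
            nxt[0] = min(max(nxt[0], 0.0), w)
            nxt[1] = min(max(nxt[1], 0.0), l)
            pos = nxt
            steps.append(StepEvent(t=t, x=float(pos[0]), y=float(pos[1]),
                                   foot=feet[step_idx % 2]))
            step_idx += 1
    return Session(
        session_id=session_id,
        steps=steps,
        room_width=w,
        room_length=l,
    )


def generate_cohort(
    k_groups: int,
    params_per_group: Sequence[PathGenParams],
    n_per_group: int,
    seed: int = 0,
) -> tuple[list[Session], dict[str, int]]:
    """Generate a labeled cohort of ``k_groups x n_per_group`` sessions.

    Returns the sessions plus the ground-truth group label of each session
    id, for parameter-recovery experiments. Per-session seeds are spawned
    from ``seed``, so the cohort is reproducible as a whole.
    """
    if len(params_per_group) != k_groups:
        raise ValueError("params_per_group must have k_groups entries")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in
                   ss.spawn(k_groups * n_per_group)]
    sessions: list[Session] = []
    labels: dict[str, int] = {}
    i = 0
    for g, base in enumerate(params_per_group):
        for j in range(n_per_group):
            sid = f"g{g}_s{j}"
            p = replace(base, seed=child_seeds[i])
            sessions.append(generate_session(p, session_id=sid))
            labels[sid] = g
            i += 1
    return sessions, labels


def separated_cohort_params() -> list[PathGenParams]:
    """Five clearly separated generator configurations for parameter-recovery
    experiments.

    Every group has a distinct bout count (a zero-within-variance feature),
    and adjacent groups additionally contrast on heading noise, turn-bias
    dispersion, or bout-length dispersion. Because three of the four
    variety dimensions are standard errors — SD over sqrt(contributing
    units) — separation must be designed on the SE scale: bout counts stay
    high (>= 50) so sampling noise in the SEs is small, and the bout-length
    SDs are chosen so the length SEs differ after the sqrt(n_bouts)
    normalization. Use these, not :data:`PRESETS`, when the question is
    whether the metrics-to-clustering pipeline can recover a known
    grouping: the presets deliberately contain qualitatively similar pairs.
    """
    return [
        PathGenParams(n_bouts=130, heading_sd_deg=8.0, turn_bias_sd_deg=3.0,
                      steps_per_bout_sd=2.0),   # many stops, straight, uniform
        PathGenParams(n_bouts=110, heading_sd_deg=45.0, turn_bias_sd_deg=3.0,
                      steps_per_bout_sd=10.0),  # high step-direction noise
        PathGenParams(n_bouts=90, heading_sd_deg=8.0, turn_bias_sd_deg=20.0,
                      steps_per_bout_sd=2.0),   # wide range of path curvature
        PathGenParams(n_bouts=70, heading_sd_deg=45.0, turn_bias_sd_deg=20.0,
                      steps_per_bout_sd=12.0),  # high on every dimension
        PathGenParams(n_bouts=50, heading_sd_deg=8.0, turn_bias_sd_deg=3.0,
                      steps_per_bout_sd=2.0),   # few stops, low variety
    ]


#: Qualitative variety presets (ordinal high/low contrasts per dimension):
#: green  — high direction variety, many stops, low shape, lowish length;
#: yellow — high shape, many stops, low direction, low length;
#: blue   — high shape and length, few stops, lowish direction;
#: red    — high shape and length, fairly few stops, low direction;
#: purple — fairly high variety on every dimension.
PRESETS: dict[str, PathGenParams] = {
    "green": PathGenParams(n_bouts=80, heading_sd_deg=40.0, turn_bias_sd_deg=2.0,
                           steps_per_bout_sd=4.0),
    "yellow": PathGenParams(n_bouts=70, heading_sd_deg=8.0, turn_bias_sd_deg=14.0,
                            steps_per_bout_sd=3.0),
    "blue": PathGenParams(n_bouts=30, heading_sd_deg=16.0, turn_bias_sd_deg=18.0,
                          steps_per_bout_sd=12.0),
    "red": PathGenParams(n_bouts=42, heading_sd_deg=9.0, turn_bias_sd_deg=17.0,
                         steps_per_bout_sd=11.0),
    "purple": PathGenParams(n_bouts=60, heading_sd_deg=30.0, turn_bias_sd_deg=12.0,
                            steps_per_bout_sd=8.0),
}
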