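"""Stepper-motor wheel kinematics for a rotary-zone cycler.

The wheel carries ``num_segments`` heater blocks and is driven by a stepper
under a trapezoidal velocity profile (constant acceleration to a cruise
velocity, cruise, symmetric deceleration; short moves degenerate to a
triangular profile).  Distances are expressed in microsteps; the microstep
count per 1-segment move is never assumed from motor specs but calibrated
from one observed single-segment transition time.

A fixed wire harness limits cumulative unidirectional rotation, so rotation
planning tracks cumulative twist and reverses direction when the short way
would exceed the limit.

Angular convention: segments are indexed 0..n-1 counterclockwise with segment
centers at (i + 1/2) * 360/n degrees; the sample bolus sits at fixed lab
angle 0, and positive twist is counterclockwise wheel rotation.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator
from scipy.optimize import brentq

from .simulate import DriveSchedule

__all__ = [
    "MotionProfile",
    "WheelLayout",
    "RotationStep",
    "RotationPlan",
    "transition_time",
    "calibrate_steps_per_segment",
    "plan_rotation",
    "plan_moves",
    "angular_position",
    "drive_temperature_schedule",
]


class MotionProfile(BaseModel):
    """Stepper settings: acceleration [usteps/s^2] and cruise velocity [usteps/s]."""

    model_config = ConfigDict(frozen=True)

    acceleration: float = 6103.52
    max_velocity: float = 4000.0

    @field_validator("acceleration", "max_velocity")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("motion parameters must be positive")
        return v


class WheelLayout(BaseModel):
    """Segment arrangement and calibrated geometry of the wheel.

    ``segment_order`` lists block ids counterclockwise from segment 0; blocks
    are conventionally arranged in order of increasing temperature.
    ``steps_per_segment`` is the calibrated microstep distance of a 1-segment
    move; ``gear_ratio`` is retained as metadata only.
    """

    model_config = ConfigDict(frozen=True)

    num_segments: int = 4
    steps_per_segment: float = 2658.56
    segment_order: tuple[str, ...] = ("load", "anneal", "extend", "denature")
    arc_span: float = 73.6
    harness_twist_limit: float = 270.0
    gear_ratio: float = 26.85

    @field_validator("num_segments")
    @classmethod
    def _segs(cls, v: int) -> int:
        if v < 2:
            raise ValueError("need at least 2 segments")
        return v

    @field_validator("steps_per_segment")
    @classmethod
    def _steps(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("steps_per_segment must be positive")
        return v

    @property
    def segment_angle(self) -> float:
        return 360.0 / self.num_segments

    def segment_index(self, block_id: str) -> int:
        try:
            return self.segment_order.index(block_id)
        except ValueError:
            raise KeyError(f"block {block_id!r} not in wheel layout") from None

    def segment_center(self, index: int) -> float:
        return (index + 0.5) * self.segment_angle


class RotationStep(BaseModel):
    """One planned wheel move: ``n_segments`` in ``direction`` (+1 = CCW)."""

    model_config = ConfigDict(frozen=True)

    from_block: str
    to_block: str
    direction: int
    n_segments: int
    start_time: float = 0.0
    duration: float = 0.0
    start_twist: float = 0.0
    end_twist: float = 0.0


class RotationPlan(BaseModel):
    """Sequence of rotation steps with the twist trajectory they imply."""

    model_config = ConfigDict(frozen=True)

    steps: tuple[RotationStep, ...] = ()

    @property
    def final_twist(self) -> float:
        return self.steps[-1].end_twist if self.steps else 0.0

    @property
    def total_rotation_time(self) -> float:
        return sum(s.duration for s in self.steps)


# ---------------------------------------------------------------------------
# trapezoidal profile arithmetic
# ---------------------------------------------------------------------------


def _move_time(distance: float, motion: MotionProfile) -> float:
    a, v = motion.acceleration, motion.max_velocity
    if distance <= 0:
        return 0.0
    if distance >= v * v / a:
        return distance / v + v / a
    return 2.0 * math.sqrt(distance / a)


def transition_time(n_segments: int, motion: MotionProfile, layout: WheelLayout) -> float:
    """Wall-clock duration of an ``n_segments`` wheel move [s].

    Trapezoidal: ``t = d/v + v/a`` for ``d >= v^2/a``; triangular
    ``t = 2 sqrt(d/a)`` for shorter moves; ``t = 0`` for ``n = 0``.
    """
    if n_segments < 0:
        raise ValueError("n_segments must be non-negative")
    return _move_time(n_segments * layout.steps_per_segment, motion)


def calibrate_steps_per_segment(
    observed_single_transition: float, motion: MotionProfile
) -> float:
    """Invert the motion profile to recover the 1-segment microstep distance.

    In the trapezoidal regime (``t >= 2 v/a``) the inversion is
    ``d = v (t - v/a)``; shorter observed times fall in the triangular
    regime where ``d = a t^2 / 4``.
    """
    a, v = motion.acceleration, motion.max_velocity
    t = observed_single_transition
    if t <= 0:
        raise ValueError("observed transition time must be positive")
    if t >= 2.0 * v / a:
        return v * (t - v / a)
    return a * t * t / 4.0


def angular_position(
    t: float, step: RotationStep, motion: MotionProfile, layout: WheelLayout
) -> float:
    """Unsigned wheel angle traversed ``t`` seconds into a move [degrees].

    Piecewise quadratic / linear / quadratic under the trapezoidal (or
    triangular) velocity profile; ``t`` is clamped to the move span.
    """
    a, v = motion.acceleration, motion.max_velocity
    d = step.n_segments * layout.steps_per_segment
    if d == 0:
        return 0.0
    total = _move_time(d, motion)
    t = min(max(t, 0.0), total)
    if d >= v * v / a:  # trapezoidal
        t_acc = v / a
        d_acc = 0.5 * v * v / a
        t_cruise_end = total - t_acc
        if t <= t_acc:
            x = 0.5 * a * t * t
        elif t <= t_cruise_end:
            x = d_acc + v * (t - t_acc)
        else:
            rem = total - t
            x = d - 0.5 * a * rem * rem
    else:  # triangular
        v_peak = math.sqrt(d * a)
        t_peak = v_peak / a
        if t <= t_peak:
            x = 0.5 * a * t * t
        else:
            rem = total - t
            x = d - 0.5 * a * rem * rem
    deg_per_step = layout.segment_angle / layout.steps_per_segment
    return x * deg_per_step


# ---------------------------------------------------------------------------
# rotation planning under the harness twist constraint
# ---------------------------------------------------------------------------


def plan_rotation(
    from_block: str,
    to_block: str,
    layout: WheelLayout,
    current_twist: float = 0.0,
) -> RotationStep:
    """Choose direction and segment count for one block-to-block move.

    Picks the direction with the fewest segments; on ties, the direction
    that reduces cumulative harness twist.  If the short way would exceed
    the twist limit, the long way is taken; if neither direction is legal
    an error names the twist state.
    """
    i = layout.segment_index(from_block)
    j = layout.segment_index(to_block)
    n = layout.num_segments
    seg = layout.segment_angle
    if i == j:
        return RotationStep(
            from_block=from_block,
            to_block=to_block,
            direction=1,
            n_segments=0,
            start_twist=current_twist,
            end_twist=current_twist,
        )
    # CCW (+1) rotation brings lower-indexed segments under the bolus:
    # engaging block j requires twist delta = (center_i - center_j) mod 360.
    k_ccw = (i - j) % n
    options = [
        (+1, k_ccw, current_twist + k_ccw * seg),
        (-1, n - k_ccw, current_twist - (n - k_ccw) * seg),
    ]
    legal = [o for o in options if abs(o[2]) <= layout.harness_twist_limit + 1e-9]
    if not legal:
        raise ValueError(
            f"no legal rotation {from_block}->{to_block}: cumulative twist "
            f"{current_twist:+.1f} deg with limit +/-{layout.harness_twist_limit} deg"
        )
    legal.sort(key=lambda o: (o[1], abs(o[2])))
    direction, k, end_twist = legal[0]
    return RotationStep(
        from_block=from_block,
        to_block=to_block,
        direction=direction,
        n_segments=k,
        start_twist=current_twist,
        end_twist=end_twist,
    )


def plan_moves(
    block_sequence: Sequence[str],
    layout: WheelLayout,
    motion: MotionProfile,
    start_time: float = 0.0,
    start_twist: float = 0.0,
    dwell_times: Sequence[float] | None = None,
) -> RotationPlan:
    """Plan a chain of moves through ``block_sequence``.

    ``dwell_times[k]`` is the hold after arriving at ``block_sequence[k+1]``;
    moves are stamped with start times and durations.
    """
    steps: list[RotationStep] = []
    twist = start_twist
    t = start_time
    for idx, (a, b) in enumerate(zip(block_sequence, block_sequence[1:])):
        step = plan_rotation(a, b, layout, twist)
        duration = transition_time(step.n_segments, motion, layout)
        step = step.model_copy(update={"start_time": t, "duration": duration})
        steps.append(step)
        twist = step.end_twist
        t += duration
        if dwell_times is not None and idx < len(dwell_times):
            t += dwell_times[idx]
    return RotationPlan(steps=tuple(steps))


# ---------------------------------------------------------------------------
# drive-temperature schedule seen by a point on the sample bolus
# ---------------------------------------------------------------------------


def _wrap(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


def _engaged_segment(
    twist: float, beta: float, layout: WheelLayout
) -> int | None:
    """Segment index under lab angle ``beta`` at wheel twist ``twist``, or None in a gap."""
    half = layout.arc_span / 2.0
    for i in range(layout.num_segments):
        u = _wrap(layout.segment_center(i) + twist - beta)
        if abs(u) <= half:
            return i
    return None


def drive_temperature_schedule(
    plan: RotationPlan,
    layout: WheelLayout,
    block_temps: Mapping[str, float | None],
    motion: MotionProfile,
    bolus_offset: float = 0.0,
    end_time: float | None = None,
) -> DriveSchedule:
    """Drive temperature vs time for a capillary point offset from bolus center.

    ``bolus_offset`` (degrees along the groove) displaces the observed point
    from the bolus center: a leading point switches blocks earlier and a
    trailing point later during each move.  Unheated blocks and inter-block
    gaps emit gap-hold (``None``) intervals.
    """
    if abs(bolus_offset) >= layout.arc_span / 2.0:
        raise ValueError("bolus_offset must lie within the engaged groove span")
    if not plan.steps:
        raise ValueError("empty rotation plan")
    beta = bolus_offset

    def temp_of(seg: int | None) -> float | None:
        if seg is None:
            return None
        return block_temps.get(layout.segment_order[seg])

    events: list[tuple[float, float | None]] = []
    first = plan.steps[0]
    # Align the wheel frame so the plan's starting block is engaged (centered
    # on the bolus) at the initial twist; twist deltas are exact segment
    # multiples, so subsequent engagements follow automatically.
    align = -layout.segment_center(layout.segment_index(first.from_block)) - (
        first.start_twist
    )
    t_cursor = first.start_time
    seg0 = _engaged_segment(align + first.start_twist, beta, layout)
    events.append((t_cursor, temp_of(seg0)))

    for step in plan.steps:
        if step.n_segments == 0:
            continue
        # dwell before this move keeps the previous temperature: nothing to emit.
        n_grid = 400 * max(step.n_segments, 1)
        ts = np.linspace(step.start_time, step.start_time + step.duration, n_grid)

        def twist_at(t: float) -> float:
            return align + step.start_twist + step.direction * angular_position(
                t - step.start_time, step, motion, layout
            )

        prev_seg = _engaged_segment(twist_at(ts[0]), beta, layout)
        for t_lo, t_hi in zip(ts, ts[1:]):
            seg = _engaged_segment(twist_at(t_hi), beta, layout)
            if seg == prev_seg:
                continue
            # refine the edge-crossing time of whichever segment boundary moved
            ref_seg = prev_seg if prev_seg is not None else seg
            half = layout.arc_span / 2.0
            center = layout.segment_center(ref_seg)

            def g(t: float) -> float:
                return abs(_wrap(center + twist_at(t) - beta)) - half

            try:
                t_cross = brentq(g, t_lo, t_hi, xtol=1e-9)
            except ValueError:
                t_cross = 0.5 * (t_lo + t_hi)
            events.append((float(t_cross), temp_of(seg)))
            prev_seg = seg

    duration = end_time if end_time is not None else (
        plan.steps[-1].start_time + plan.steps[-1].duration
    )
    duration = max(duration, events[-1][0] + 1e-9)
    return DriveSchedule(breakpoints=tuple(events), duration=duration).merged()
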