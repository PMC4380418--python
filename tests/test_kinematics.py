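"""Wheel motion: trapezoidal timing, calibration, planning, bolus schedules."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rztc import (
    WheelLayout,
    angular_position,
    calibrate_steps_per_segment,
    drive_temperature_schedule,
    plan_moves,
    plan_rotation,
    transition_time,
)

BLOCK_TEMPS = {"load": None, "anneal": 60.0, "extend": 72.0, "denature": 98.0}


class TestTransitionTime:
    def test_zero_segments(self, motion, layout):
        assert transition_time(0, motion, layout) == 0.0

    def test_calibrated_single_segment(self, motion, layout):
        assert transition_time(1, motion, layout) == pytest.approx(1.32, abs=1e-12)

    def test_two_segment_time(self, motion, layout):
        assert transition_time(2, motion, layout) == pytest.approx(1.99, abs=0.01)

    def test_constant_velocity_increment(self, motion, layout):
        """t(n+1) - t(n) = d/v in the trapezoidal regime for all n."""
        dv = layout.steps_per_segment / motion.max_velocity
        for n in range(1, 6):
            delta = transition_time(n + 1, motion, layout) - transition_time(
                n, motion, layout
            )
            assert delta == pytest.approx(dv, rel=1e-12)

    def test_triangular_regime_short_move(self, motion):
        """A move too short to reach cruise follows t = 2 sqrt(d/a)."""
        short = WheelLayout(steps_per_segment=100.0)
        t = transition_time(1, motion, short)
        assert t == pytest.approx(2.0 * math.sqrt(100.0 / motion.acceleration))
        assert t < 2.0 * motion.max_velocity / motion.acceleration


class TestCalibration:
    def test_documented_value(self, motion):
        # d = v (t - v/a) with the stock settings at t = 1.32 s
        d = calibrate_steps_per_segment(1.32, motion)
        assert d == pytest.approx(2660, rel=0.01)

    def test_round_trip_trapezoidal(self, motion):
        d = calibrate_steps_per_segment(1.32, motion)
        layout = WheelLayout(steps_per_segment=d)
        assert transition_time(1, motion, layout) == pytest.approx(1.32, abs=1e-12)

    def test_round_trip_triangular(self, motion):
        t_obs = 0.9 * 2.0 * motion.max_velocity / motion.acceleration
        d = calibrate_steps_per_segment(t_obs, motion)
        layout = WheelLayout(steps_per_segment=d)
        assert transition_time(1, motion, layout) == pytest.approx(t_obs, rel=1e-12)

    def test_nonpositive_time_rejected(self, motion):
        with pytest.raises(ValueError):
            calibrate_steps_per_segment(0.0, motion)


class TestAngularPosition:
    def test_endpoints(self, motion, layout):
        step = plan_rotation("anneal", "denature", layout)  # 2 segments
        duration = transition_time(step.n_segments, motion, layout)
        step = step.model_copy(update={"duration": duration})
        assert angular_position(0.0, step, motion, layout) == 0.0
        assert angular_position(duration, step, motion, layout) == pytest.approx(
            step.n_segments * 90.0
        )

    def test_matches_velocity_quadrature(self, motion, layout):
        """Closed-form position equals numeric integration of the velocity."""
        a, v = motion.acceleration, motion.max_velocity
        step = plan_rotation("anneal", "extend", layout)  # 1 segment
        d = layout.steps_per_segment
        total = transition_time(1, motion, layout)
        step = step.model_copy(update={"duration": total})

        def velocity(t):
            t_acc = v / a
            if t < t_acc:
                return a * t
            if t < total - t_acc:
                return v
            return a * (total - t)

        ts = np.linspace(0.0, total, 20001)
        vs = np.array([velocity(t) for t in ts])
        for frac in (0.25, 0.5, 0.75):
            t_q = frac * total
            mask = ts <= t_q
            x = np.trapezoid(vs[mask], ts[mask])  # usteps
            expected = x * 90.0 / layout.steps_per_segment
            got = angular_position(t_q, step, motion, layout)
            assert got == pytest.approx(expected, abs=0.05)

    def test_monotone_within_move(self, motion, layout):
        step = plan_rotation("anneal", "denature", layout)
        total = transition_time(step.n_segments, motion, layout)
        step = step.model_copy(update={"duration": total})
        ts = np.linspace(0, total, 500)
        xs = [angular_position(t, step, motion, layout) for t in ts]
        assert all(b >= a for a, b in zip(xs, xs[1:]))


class TestPlanRotation:
    def test_adjacent_is_one_segment(self, layout):
        step = plan_rotation("anneal", "extend", layout)
        assert step.n_segments == 1

    def test_tie_break_reduces_twist(self, layout):
        """Opposite blocks: both ways are 2 segments; untwist wins."""
        step = plan_rotation("anneal", "denature", layout, current_twist=180.0)
        assert step.n_segments == 2
        assert abs(step.end_twist) < 180.0

    def test_reverses_at_harness_limit(self, layout):
        """Same-direction stepping must reverse before exceeding 270 degrees."""
        sequence = ["denature", "extend", "anneal", "load", "denature", "extend"]
        twist = 0.0
        long_way_taken = False
        for a, b in zip(sequence, sequence[1:]):
            step = plan_rotation(a, b, layout, twist)
            twist = step.end_twist
            assert abs(twist) <= layout.harness_twist_limit
            if step.n_segments == 3:
                long_way_taken = True
        assert long_way_taken

    def test_error_names_twist_state(self):
        cramped = WheelLayout(harness_twist_limit=45.0)
        with pytest.raises(ValueError, match="twist"):
            plan_rotation("anneal", "extend", cramped, current_twist=40.0)

    @given(
        indices=st.lists(st.integers(min_value=0, max_value=3), min_size=2, max_size=40)
    )
    @settings(derandomize=True, max_examples=100)
    def test_twist_limit_never_violated(self, indices, layout):
        blocks = [layout.segment_order[i] for i in indices]
        twist = 0.0
        for a, b in zip(blocks, blocks[1:]):
            step = plan_rotation(a, b, layout, twist)
            twist = step.end_twist
            assert abs(twist) <= layout.harness_twist_limit + 1e-9


class TestDriveSchedule:
    def test_stationary_wheel_constant_temperature(self, motion, layout):
        plan = plan_moves(["anneal", "anneal"], layout, motion)
        sched = drive_temperature_schedule(
            plan, layout, BLOCK_TEMPS, motion, end_time=10.0
        )
        assert sched.breakpoints == ((0.0, 60.0),)

    def test_gap_reported_between_blocks(self, motion, layout):
        plan = plan_moves(["anneal", "extend"], layout, motion)
        sched = drive_temperature_schedule(plan, layout, BLOCK_TEMPS, motion)
        temps = [temp for _, temp in sched.breakpoints]
        assert temps[0] == 60.0
        assert None in temps  # insulating gap between adjacent blocks
        assert temps[-1] == 72.0

    def test_leading_trailing_switch_time_offset(self, motion, layout):
        """During cruise, points +/- delta degrees switch 2*delta/omega apart."""
        from rztc import RotationPlan

        # force the 3-segment long way so the middle crossing happens at cruise
        step = plan_rotation("anneal", "extend", layout, current_twist=-270.0)
        assert step.n_segments == 3
        duration = transition_time(3, motion, layout)
        plan = RotationPlan(steps=(step.model_copy(update={"duration": duration}),))
        delta = 8.0
        crossings = {}
        for off in (-delta, +delta):
            sched = drive_temperature_schedule(
                plan, layout, BLOCK_TEMPS, motion, bolus_offset=off
            )
            # entry into the denature block, traversed mid-move at cruise speed
            t98 = [t for t, temp in sched.breakpoints if temp == 98.0]
            crossings[off] = t98[0]
        omega = motion.max_velocity / layout.steps_per_segment * 90.0  # deg/s
        expected = 2.0 * delta / omega
        got = abs(crossings[+delta] - crossings[-delta])
        assert got == pytest.approx(expected, abs=2e-3)

    def test_offset_outside_groove_rejected(self, motion, layout):
        plan = plan_moves(["anneal", "extend"], layout, motion)
        with pytest.raises(ValueError):
            drive_temperature_schedule(
                plan, layout, BLOCK_TEMPS, motion, bolus_offset=50.0
            )
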