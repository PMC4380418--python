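"""Sample temperature simulation under piecewise-constant drive temperatures.

The engaged heater block forces the sample lump toward its temperature as a
bounded exponential, ``T(t) = T_B + (T_start - T_B) exp(-(t - t_start)/tau)``,
evaluated in closed form on each constant-drive interval of a
:class:`DriveSchedule`.  Intervals whose drive temperature is ``None`` model
traversal of the insulating gap between blocks: the sample holds its current
temperature (adiabatic hold).

Also provides the closed-form settle time ``time_to_within`` and the
rotation-plus-settle ``ramp_metrics`` used to express effective ramp rates.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator

from .thermal import ResponseModel

__all__ = [
    "DriveSchedule",
    "SimulatedTrace",
    "simulate",
    "time_to_within",
    "ramp_metrics",
]


class DriveSchedule(BaseModel):
    """Piecewise-constant drive temperature seen by the sample.

    ``breakpoints`` is an ordered list of ``(time_s, temp_C_or_None)``; each
    entry starts an interval that lasts until the next breakpoint (the last
    until ``duration``).  ``None`` marks a gap-hold interval.
    """

    model_config = ConfigDict(frozen=True)

    breakpoints: tuple[tuple[float, float | None], ...]
    duration: float

    @model_validator(mode="after")
    def _check(self) -> "DriveSchedule":
        if not self.breakpoints:
            raise ValueError("schedule must contain at least one breakpoint")
        times = [t for t, _ in self.breakpoints]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("breakpoint times must be strictly increasing")
        if self.duration < times[-1]:
            raise ValueError("duration must cover the last breakpoint")
        return self

    def merged(self) -> "DriveSchedule":
        """Collapse consecutive breakpoints sharing the same drive temperature."""
        kept: list[tuple[float, float | None]] = []
        for t, temp in self.breakpoints:
            if kept and kept[-1][1] == temp:
                continue
            kept.append((t, temp))
        return DriveSchedule(breakpoints=tuple(kept), duration=self.duration)


class SimulatedTrace(BaseModel):
    """Sampled sample-temperature history with the model metadata used."""

    model_config = ConfigDict(frozen=True, arbitrary_types_allowed=True)

    times: tuple[float, ...]
    temperatures: tuple[float, ...]
    tau: float
    schedule_id: str = ""

    @model_validator(mode="after")
    def _check(self) -> "SimulatedTrace":
        if len(self.times) != len(self.temperatures):
            raise ValueError("times and temperatures must have equal length")
        if not all(map(math.isfinite, self.temperatures)):
            raise ValueError("temperatures must be finite")
        return self

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.temperatures)


def _interval_ends(schedule: DriveSchedule) -> list[tuple[float, float, float | None]]:
    """(start, end, drive) triples covering [t0, duration]."""
    bps = schedule.breakpoints
    out = []
    for i, (t, temp) in enumerate(bps):
        end = bps[i + 1][0] if i + 1 < len(bps) else schedule.duration
        out.append((t, end, temp))
    return out


def simulate(
    schedule: DriveSchedule,
    model: ResponseModel,
    initial_temp: float,
    dt: float = 0.1,
    schedule_id: str = "",
) -> SimulatedTrace:
    """Closed-form sample response to a drive schedule, sampled every ``dt``.

    Within each interval the solution is exact (the bounded exponential), so
    ``dt`` controls output sampling only, not accuracy.  Heating and cooling
    use ``model.tau_for`` so an asymmetric time-constant pair is honoured.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    intervals = _interval_ends(schedule)
    t0 = intervals[0][0]
    times = np.arange(t0, schedule.duration + 0.5 * dt, dt)
    temps = np.empty_like(times)

    current = float(initial_temp)
    for start, end, drive in intervals:
        mask = (times >= start) & (times < end)
        if drive is None:
            temps[mask] = current
        else:
            tau = model.tau_for(heating=drive >= current)
            temps[mask] = drive + (current - drive) * np.exp(
                -(times[mask] - start) / tau
            )
            current = drive + (current - drive) * math.exp(-(end - start) / tau)
    # final sample exactly at duration
    last = intervals[-1]
    mask = times >= last[1]
    if mask.any():
        temps[mask] = current
    return SimulatedTrace(
        times=tuple(times.tolist()),
        temperatures=tuple(temps.tolist()),
        tau=model.time_constant,
        schedule_id=schedule_id,
    )


def time_to_within(
    model: ResponseModel, delta_initial: float, delta_target: float
) -> float:
    """Time for a first-order response to close an initial gap to a target gap.

    ``t = tau * ln(delta_initial / delta_target)`` — e.g. the time to come
    within 1 degC of the final temperature after a 36 degC step.
    """
    if delta_target <= 0 or delta_initial <= 0:
        raise ValueError("temperature gaps must be positive")
    if delta_target > delta_initial:
        raise ValueError("target gap cannot exceed initial gap")
    return model.time_constant * math.log(delta_initial / delta_target)


def ramp_metrics(
    rotation_time: float, settle_time: float, delta_temp: float
) -> dict[str, float]:
    """Total transition time and effective ramp rate for one zone change.

    ``total_time = rotation + settle``; ``effective_rate = delta_temp / total``.
    """
    if rotation_time < 0 or settle_time < 0:
        raise ValueError("times must be non-negative")
    total = rotation_time + settle_time
    if total == 0:
        raise ValueError("total transition time must be positive")
    return {"total_time": total, "effective_rate": delta_temp / total}
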