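"""Fitting the first-order thermal response to logged temperature traces.

A cycling trace alternates between two plateau temperatures.  The analysis
pipeline mirrors how thermocouple logs are reduced in practice:

1. ``segment_cycles`` — partition the trace at threshold crossings into
   alternating rising and falling transitions (each segment keeps half of
   the surrounding plateaus for baseline estimation);
2. ``baseline_align_average`` — baseline-correct each segment to common
   plateau asymptotes, time-shift align on the 50%-crossing, and average
   pointwise on a common grid;
3. ``fit_exponential`` — two-parameter (tau, t0) fit of the bounded
   exponential, seeded by solving the model exactly at two data points and
   refined by maximizing R^2;
4. ``rise_fall_report`` — settle times and effective ramp rates to within
   1 degC and 0.1 degC of the final temperature.

Plateau asymptotes are taken from 10%-trimmed means of the pre/post
transition samples; segmentation thresholds default to 10% and 90% of the
plateau-to-plateau span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import trim_mean

from .simulate import ramp_metrics, time_to_within
from .thermal import ResponseModel

__all__ = [
    "TemperatureTrace",
    "TraceSegment",
    "AveragedSegment",
    "FitResult",
    "segment_cycles",
    "baseline_align_average",
    "fit_exponential",
    "rise_fall_report",
]

#: fractions of span at which the two-point initialization samples the model
INIT_FRACTIONS = (0.33, 0.80)
#: trim fraction for plateau (asymptote) estimation
PLATEAU_TRIM = 0.10
#: default segmentation thresholds as fractions of the plateau span
THRESHOLD_FRACTIONS = (0.10, 0.90)


@dataclass(frozen=True)
class TemperatureTrace:
    """A sampled temperature time series (logged or synthetic)."""

    times: np.ndarray
    temperatures: np.ndarray
    sampling_rate: float = 10.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.temperatures, dtype=float)
        if t.size != y.size:
            raise ValueError("times and temperatures must have equal length")
        if t.size < 2:
            raise ValueError("trace needs at least 2 samples")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("trace values must be finite")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "temperatures", y)


@dataclass(frozen=True)
class TraceSegment:
    """One transition (plus surrounding plateau halves) cut from a trace."""

    times: np.ndarray
    temperatures: np.ndarray
    direction: str  # "rising" | "falling"


@dataclass(frozen=True)
class AveragedSegment:
    """Baseline-corrected, aligned, averaged transition."""

    times: np.ndarray
    temperatures: np.ndarray
    direction: str
    t_start: float  # common pre-transition plateau [degC]
    t_end: float  # common post-transition plateau [degC]
    lags: tuple[float, ...] = ()  # per-input alignment shifts [s]


@dataclass(frozen=True)
class FitResult:
    """Two-parameter exponential fit of one transition."""

    model: ResponseModel
    r_squared: float
    direction: str
    fit_range: tuple[float, float]
    t_start: float
    t_end: float
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------


def _plateau_levels(y: np.ndarray) -> tuple[float, float]:
    """Low/high plateau estimates via trimmed means of the two level clusters."""
    mid = 0.5 * (np.min(y) + np.max(y))
    low = y[y < mid]
    high = y[y >= mid]
    if low.size == 0 or high.size == 0:
        m = float(np.mean(y))
        return m, m
    return (
        float(trim_mean(low, PLATEAU_TRIM)),
        float(trim_mean(high, PLATEAU_TRIM)),
    )


def segment_cycles(
    trace: TemperatureTrace,
    threshold_low: float | None = None,
    threshold_high: float | None = None,
) -> list[TraceSegment]:
    """Split a cycling trace into alternating rising/falling transitions.

    Thresholds default to 10% and 90% of the span between the low and high
    plateaus.  A transition is counted only when the trace traverses the
    full band between the thresholds (hysteresis, so plateau noise cannot
    trigger spurious segments).  Each returned segment spans from midway
    through the preceding plateau to midway through the following one.
    Returns an empty list if the trace never crosses both thresholds.
    """
    t, y = trace.times, trace.temperatures
    low_p, high_p = _plateau_levels(y)
    span = high_p - low_p
    if threshold_low is None:
        threshold_low = low_p + THRESHOLD_FRACTIONS[0] * span
    if threshold_high is None:
        threshold_high = low_p + THRESHOLD_FRACTIONS[1] * span
    if threshold_high <= threshold_low:
        return []
    mid = 0.5 * (threshold_low + threshold_high)

    # hysteresis state machine over the low/high bands
    events: list[tuple[int, str]] = []  # (index of first sample past mid, direction)
    state: str | None = None
    pending: int | None = None
    for i in range(y.size):
        if y[i] <= threshold_low:
            if state == "high" and pending is not None:
                events.append((pending, "falling"))
            state, pending = "low", None
        elif y[i] >= threshold_high:
            if state == "low" and pending is not None:
                events.append((pending, "rising"))
            state, pending = "high", None
        else:
            if pending is None and state is not None:
                pending = i  # left a plateau band; traversal in progress
    # refine event indices: nearest midpoint crossing
    refined: list[tuple[int, str]] = []
    for idx, direction in events:
        j = idx
        if direction == "rising":
            while j < y.size - 1 and y[j] < mid:
                j += 1
        else:
            while j < y.size - 1 and y[j] > mid:
                j += 1
        refined.append((j, direction))

    if not refined:
        return []
    segments: list[TraceSegment] = []
    bounds = [0] + [
        (a + b) // 2 for (a, _), (b, _) in zip(refined, refined[1:])
    ] + [y.size - 1]
    for k, (idx, direction) in enumerate(refined):
        lo, hi = bounds[k], bounds[k + 1]
        segments.append(
            TraceSegment(
                times=t[lo : hi + 1].copy(),
                temperatures=y[lo : hi + 1].copy(),
                direction=direction,
            )
        )
    return segments


# ---------------------------------------------------------------------------
# baseline correction, alignment, averaging
# ---------------------------------------------------------------------------


def _segment_plateaus(seg: TraceSegment) -> tuple[float, float]:
    """(start, end) asymptote estimates for one segment (trimmed means)."""
    lo, hi = _plateau_levels(seg.temperatures)
    if seg.direction == "rising":
        return lo, hi
    return hi, lo


def _midpoint_crossing(seg: TraceSegment, t_start: float, t_end: float) -> float:
    """Interpolated time at which the segment crosses 50% of its span."""
    mid = 0.5 * (t_start + t_end)
    y = seg.temperatures
    rising = seg.direction == "rising"
    sign = 1.0 if rising else -1.0
    above = sign * (y - mid) >= 0
    # first sample past the midpoint with its predecessor before it
    idx = np.flatnonzero(above[1:] & ~above[:-1])
    if idx.size == 0:
        raise ValueError("segment never crosses its midpoint")
    i = int(idx[0]) + 1
    t0, t1 = seg.times[i - 1], seg.times[i]
    y0, y1 = y[i - 1], y[i]
    if y1 == y0:
        return float(t1)
    return float(t0 + (mid - y0) * (t1 - t0) / (y1 - y0))


def baseline_align_average(segments: list[TraceSegment]) -> AveragedSegment:
    """Baseline-correct, time-shift align, and average same-direction segments.

    Each segment is affinely rescaled so its plateau asymptotes match the
    across-segment mean plateaus, shifted so its 50%-crossing sits at t = 0,
    then linearly interpolated onto a common grid and averaged pointwise.
    """
    if not segments:
        raise ValueError("need at least one segment")
    directions = {s.direction for s in segments}
    if len(directions) > 1:
        raise ValueError("cannot average rising and falling segments together")
    direction = segments[0].direction

    plateaus = [_segment_plateaus(s) for s in segments]
    t_start = float(np.mean([p[0] for p in plateaus]))
    t_end = float(np.mean([p[1] for p in plateaus]))

    shifted: list[tuple[np.ndarray, np.ndarray]] = []
    lags: list[float] = []
    for seg, (s0, s1) in zip(segments, plateaus):
        scale = (t_end - t_start) / (s1 - s0) if s1 != s0 else 1.0
        y = (seg.temperatures - s0) * scale + t_start
        corrected = TraceSegment(times=seg.times, temperatures=y, direction=direction)
        lag = _midpoint_crossing(corrected, t_start, t_end)
        shifted.append((seg.times - lag, y))
        lags.append(lag)

    dt = float(np.median([np.median(np.diff(t)) for t, _ in shifted]))
    lo = max(t[0] for t, _ in shifted)
    hi = min(t[-1] for t, _ in shifted)
    if hi <= lo:
        raise ValueError("segments do not overlap after alignment")
    grid = np.arange(lo, hi + 0.5 * dt, dt)
    stack = np.vstack([np.interp(grid, t, y) for t, y in shifted])
    return AveragedSegment(
        times=grid,
        temperatures=stack.mean(axis=0),
        direction=direction,
        t_start=t_start,
        t_end=t_end,
        lags=tuple(lags),
    )


# ---------------------------------------------------------------------------
# two-parameter exponential fit
# ---------------------------------------------------------------------------


def _response(t: np.ndarray, tau: float, t0: float, t_start: float, t_end: float):
    """Bounded exponential from t0; flat at t_start before engagement."""
    out = np.full_like(t, t_start, dtype=float)
    after = t >= t0
    out[after] = t_end + (t_start - t_end) * np.exp(-(t[after] - t0) / tau)
    return out


def _two_point_init(
    t: np.ndarray, y: np.ndarray, t_start: float, t_end: float
) -> tuple[float, float]:
    """Solve the response model exactly at two data points near 33%/80% of span."""
    frac = (y - t_start) / (t_end - t_start)
    candidates = []
    for target in INIT_FRACTIONS:
        k = int(np.argmin(np.abs(frac - target)))
        candidates.append(k)
    k1, k2 = candidates
    if k1 == k2:
        k2 = min(k1 + 1, t.size - 1)
    f1 = float(np.clip(frac[k1], 1e-6, 1 - 1e-6))
    f2 = float(np.clip(frac[k2], 1e-6, 1 - 1e-6))
    t1, t2 = float(t[k1]), float(t[k2])
    denom = np.log((1 - f1) / (1 - f2))
    if denom == 0 or t2 == t1:
        tau = max((t[-1] - t[0]) / 5.0, 1e-6)
        return tau, t1
    tau = (t2 - t1) / denom
    if tau <= 0:
        tau = max((t[-1] - t[0]) / 5.0, 1e-6)
    t0 = t1 + tau * np.log(1 - f1)
    return float(tau), float(t0)


def fit_exponential(
    segment: TraceSegment | AveragedSegment,
    t_start: float | None = None,
    t_end: float | None = None,
) -> FitResult:
    """Fit (tau, t0) of the bounded exponential to one transition.

    Asymptotes default to the segment's trimmed-mean plateau estimates.  The
    fit is seeded by solving the model exactly at two data points (nearest
    33% and 80% of span) and refined by least squares over the full segment
    (equivalently, maximizing R^2); the refinement never degrades the seed.
    """
    t = np.asarray(segment.times, dtype=float)
    y = np.asarray(segment.temperatures, dtype=float)
    if t.size < 5:
        raise ValueError("segment needs at least 5 samples to fit")
    if t_start is None or t_end is None:
        if isinstance(segment, AveragedSegment):
            p0, p1 = segment.t_start, segment.t_end
        else:
            p0, p1 = _segment_plateaus(segment)
        t_start = p0 if t_start is None else t_start
        t_end = p1 if t_end is None else t_end
    if t_start == t_end:
        raise ValueError("asymptotes coincide; no transition to fit")

    warnings: list[str] = []
    sign = 1.0 if t_end > t_start else -1.0
    increments = np.diff(y) * sign
    span = abs(t_end - t_start)
    if np.any(increments < -0.25 * span):
        warnings.append("segment is non-monotone beyond noise tolerance")

    tau0, t00 = _two_point_init(t, y, t_start, t_end)

    def residuals(params: np.ndarray) -> np.ndarray:
        tau, t0 = params
        return _response(t, tau, t0, t_start, t_end) - y

    sol = least_squares(
        residuals,
        x0=[tau0, t00],
        bounds=([1e-12, -np.inf], [np.inf, np.inf]),
        xtol=1e-14,
        ftol=1e-14,
        gtol=1e-14,
    )
    tau, t0 = float(sol.x[0]), float(sol.x[1])
    ss_res = float(np.sum(sol.fun**2))
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    direction = getattr(segment, "direction", "rising" if sign > 0 else "falling")
    return FitResult(
        model=ResponseModel(time_constant=tau, offset=t0),
        r_squared=r2,
        direction=direction,
        fit_range=(float(t[0]), float(t[-1])),
        t_start=float(t_start),
        t_end=float(t_end),
        warnings=tuple(warnings),
    )


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def rise_fall_report(
    fit: FitResult | ResponseModel,
    delta_initial: float,
    thresholds: tuple[float, ...] = (1.0, 0.1),
    rotation_time: float = 0.0,
) -> list[dict[str, float]]:
    """Settle times and ramp rates to within each threshold of the end temperature.

    For a step of ``delta_initial`` degC, each row reports the closed-form
    time to come within ``threshold`` degC of the final temperature, the
    sample ramp rate ``(delta_initial - threshold)/time``, and (when a
    ``rotation_time`` is supplied) the total transition time and effective
    rate including the wheel rotation.
    """
    model = fit.model if isinstance(fit, FitResult) else fit
    rows: list[dict[str, float]] = []
    for thr in thresholds:
        if thr >= delta_initial:
            rows.append(
                {"threshold": thr, "time": 0.0, "rate": 0.0,
                 "total_time": rotation_time, "effective_rate": 0.0}
            )
            continue
        t_settle = time_to_within(model, delta_initial, thr)
        moved = delta_initial - thr
        row = {"threshold": thr, "time": t_settle, "rate": moved / t_settle}
        metrics = ramp_metrics(rotation_time, t_settle, moved)
        row["total_time"] = metrics["total_time"]
        row["effective_rate"] = metrics["effective_rate"]
        rows.append(row)
    return rows
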