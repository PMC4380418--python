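"""Synthetic data generation and the cycler configuration model.

``CyclerConfig`` bundles everything that defines one physical cycler:
materials table, capillary, heater blocks, wheel layout and motion profile.
The shipped default (``data/cycler_default.yaml``) describes a four-segment
wheel of 55 g aluminum blocks spanning 73.6 degrees each on a 7.62 cm wheel,
a 406/794 um FEP sample capillary holding ~4 uL, and the stock stepper
settings — enough to exercise every operation in the package without
hardware.

``generate_trace`` turns a drive schedule plus a true time constant into a
thermocouple-like logged trace: closed-form response sampled at ~10 Hz with
seeded i.i.d. Gaussian noise (default sigma 0.3 degC, which yields fitted
R^2 near 0.992) and optional linear sensor drift.
"""

from __future__ import annotations

import math

import numpy as np
from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .kinematics import MotionProfile, WheelLayout
from .simulate import DriveSchedule, simulate
from .thermal import (
    BoreContents,
    CapillarySpec,
    EngagementGeometry,
    HeaterBlockSpec,
    Material,
    ResponseModel,
)
from .traces import TemperatureTrace

__all__ = [
    "SyntheticTraceSpec",
    "CyclerConfig",
    "generate_trace",
    "square_wave_schedule",
]

SCHEMA_VERSION = 1


class SyntheticTraceSpec(BaseModel):
    """Recipe for a reproducible synthetic thermocouple trace."""

    model_config = ConfigDict(frozen=True)

    tau: float
    schedule: DriveSchedule
    initial_temp: float
    noise_sigma: float = 0.3
    sampling_rate: float = 10.0
    seed: int = 0
    drift_slope: float = 0.0  # degC/s

    @field_validator("tau", "sampling_rate")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("tau and sampling_rate must be positive")
        return v

    @field_validator("noise_sigma")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("noise_sigma must be non-negative")
        return v


class CyclerConfig(BaseModel):
    """A complete cycler definition (the digital twin's hardware description)."""

    model_config = ConfigDict(frozen=True)

    schema_version: int = SCHEMA_VERSION
    name: str = "cycler"
    materials: dict[str, Material]
    capillary: CapillarySpec
    blocks: tuple[HeaterBlockSpec, ...]
    layout: WheelLayout
    motion: MotionProfile
    sample_volume_ul: float = 4.0

    @model_validator(mode="after")
    def _cross_check(self) -> "CyclerConfig":
        block_ids = {b.id for b in self.blocks}
        for seg in self.layout.segment_order:
            if seg not in block_ids:
                raise ValueError(f"layout names unknown block {seg!r}")
        if len(self.blocks) != self.layout.num_segments:
            raise ValueError("number of blocks must match wheel segments")
        return self

    def block(self, block_id: str) -> HeaterBlockSpec:
        for b in self.blocks:
            if b.id == block_id:
                return b
        raise KeyError(block_id)

    def block_temps(self) -> dict[str, float | None]:
        return {b.id: b.setpoint for b in self.blocks}

    def engagement(self) -> EngagementGeometry:
        """Contact length implied by the nominal sample volume filling the bore."""
        bore_area = math.pi / 4.0 * self.capillary.inner_diameter**2
        return EngagementGeometry(
            contact_length=self.sample_volume_ul * 1e-9 / bore_area
        )

    def bore_contents(self) -> BoreContents:
        return BoreContents(sample_material=self.materials["water"])


def square_wave_schedule(
    low: float,
    high: float,
    dwell: float,
    cycles: int,
    start_low: bool = True,
    lead_in: float = 0.0,
) -> DriveSchedule:
    """Alternating two-temperature drive, ``cycles`` full periods.

    Mirrors a thermocouple characterization run: the wheel shuttles the
    sample between two adjacent blocks with a fixed dwell on each.  A
    positive ``lead_in`` prepends a hold at the opposite temperature so the
    first transition has a plateau before it (``cycles`` full rise/fall
    pairs then appear in the trace).
    """
    if cycles < 1:
        raise ValueError("need at least one cycle")
    temps = (low, high) if start_low else (high, low)
    breakpoints = []
    t = 0.0
    if lead_in > 0:
        breakpoints.append((0.0, temps[1]))
        t = lead_in
    for _ in range(cycles):
        for temp in temps:
            breakpoints.append((t, temp))
            t += dwell
    return DriveSchedule(breakpoints=tuple(breakpoints), duration=t)


def generate_trace(spec: SyntheticTraceSpec) -> TemperatureTrace:
    """Simulate the response and add seeded measurement noise and drift.

    With ``noise_sigma = 0`` and ``drift_slope = 0`` the output equals the
    closed-form simulation at the sample times; a fixed seed regenerates the
    trace bit-identically.
    """
    dt = 1.0 / spec.sampling_rate
    model = ResponseModel(time_constant=spec.tau)
    clean = simulate(spec.schedule, model, spec.initial_temp, dt=dt)
    t, y = clean.arrays()
    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        y = y + rng.normal(0.0, spec.noise_sigma, size=y.shape)
    if spec.drift_slope != 0.0:
        y = y + spec.drift_slope * (t - t[0])
    return TemperatureTrace(times=t, temperatures=y, sampling_rate=spec.sampling_rate)
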