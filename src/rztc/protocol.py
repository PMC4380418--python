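"""Compile PCR thermal programs onto the rotating wheel.

A PCR protocol is a sequence of temperature dwells (optionally preceded by a
hot start and followed by a final elongation), grouped into stages repeated
for a cycle count.  Compilation maps each protocol temperature to a wheel
block arranged in order of increasing temperature, plans the rotations
between consecutive temperatures under the harness-twist constraint, and
lays out the run as alternating rotation and dwell events.

Timing convention: each dwell timer starts when its rotation stops (thermal
settling is reported separately by :func:`validate`, not added to the
timeline).  The initial rotation from the load segment is part of the run;
the final unload rotation is not.  A block whose setpoint changes mid-run
(e.g. a 96 degC hot-start block re-targeted to 90 degC for stage-2 cycling)
stabilizes concurrently with cycling; compilation only checks that the
stabilization completes before the block is next used.
"""

from __future__ import annotations

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

from .kinematics import (
    MotionProfile,
    RotationPlan,
    RotationStep,
    WheelLayout,
    plan_rotation,
    transition_time,
)
from .thermal import ResponseModel

__all__ = [
    "ProtocolStep",
    "ProtocolStage",
    "SetpointChange",
    "PCRProtocol",
    "BlockAssignment",
    "TimelineEvent",
    "CompiledRun",
    "assign_blocks",
    "compile_protocol",
    "validate",
]


class ProtocolStep(BaseModel):
    """One dwell: hold ``temp`` [degC] for ``dwell`` [s]."""

    model_config = ConfigDict(frozen=True)

    temp: float
    dwell: float
    label: str = ""

    @field_validator("dwell")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("dwell must be positive")
        return v


class ProtocolStage(BaseModel):
    """``cycles`` repetitions of an ordered step list."""

    model_config = ConfigDict(frozen=True)

    cycles: int
    steps: tuple[ProtocolStep, ...]

    @field_validator("cycles")
    @classmethod
    def _nonneg(cls, v: int) -> int:
        if v < 0:
            raise ValueError("cycle count must be non-negative")
        return v


class SetpointChange(BaseModel):
    """Re-target the block hosting ``from_temp`` to ``to_temp`` mid-run.

    ``after_stage`` triggers the change: 0 = when the hot start ends,
    k >= 1 = when stage k (1-based) ends.  ``stabilization_time`` [s] is the
    user-supplied settling allowance before the block may be used at its new
    temperature (it runs concurrently with cycling on other blocks).
    """

    model_config = ConfigDict(frozen=True)

    from_temp: float
    to_temp: float
    after_stage: int = 0
    stabilization_time: float = 0.0


class PCRProtocol(BaseModel):
    """A thermal program: hot start, cycled stages, final step, setpoint changes."""

    model_config = ConfigDict(frozen=True)

    name: str = ""
    hot_start: ProtocolStep | None = None
    stages: tuple[ProtocolStage, ...] = ()
    final_step: ProtocolStep | None = None
    setpoint_changes: tuple[SetpointChange, ...] = ()

    def temperature_visits(self) -> list[tuple[float, float, str]]:
        """Chronological (temp, dwell, label) visits, cycles expanded."""
        visits: list[tuple[float, float, str]] = []
        if self.hot_start is not None:
            visits.append((self.hot_start.temp, self.hot_start.dwell, "hot_start"))
        for si, stage in enumerate(self.stages, start=1):
            for c in range(stage.cycles):
                for step in stage.steps:
                    label = step.label or f"stage{si}"
                    visits.append((step.temp, step.dwell, f"{label} c{c + 1}"))
        if self.final_step is not None:
            visits.append((self.final_step.temp, self.final_step.dwell, "final"))
        return visits


class BlockAssignment(BaseModel):
    """Mapping of protocol temperatures onto wheel segments.

    ``wheel`` is the derived layout whose ``segment_order`` lists the
    assigned block ids counterclockwise; ``temp_to_block`` maps every
    protocol temperature (including pre-change setpoints) to its block;
    ``block_setpoints`` gives each block's initial setpoint (None for an
    unheated load segment).
    """

    model_config = ConfigDict(frozen=True)

    wheel: WheelLayout
    temp_to_block: dict[float, str]
    block_setpoints: dict[str, float | None]
    load_block: str

    @model_validator(mode="after")
    def _check(self) -> "BlockAssignment":
        for t, b in self.temp_to_block.items():
            if b not in self.wheel.segment_order:
                raise ValueError(f"assigned block {b!r} not on wheel")
        return self


class TimelineEvent(BaseModel):
    """One compiled event: a rotation or a dwell."""

    model_config = ConfigDict(frozen=True)

    kind: str  # "rotation" | "dwell"
    label: str
    block: str
    temp: float | None
    start: float
    duration: float

    @property
    def end(self) -> float:
        return self.start + self.duration


class CompiledRun(BaseModel):
    """Realized protocol: rotation plan, event timeline, total duration."""

    model_config = ConfigDict(frozen=True)

    protocol_name: str
    events: tuple[TimelineEvent, ...]
    plan: RotationPlan
    total_duration: float
    warnings: tuple[str, ...] = ()

    @property
    def total_rotation_time(self) -> float:
        return sum(e.duration for e in self.events if e.kind == "rotation")

    @property
    def total_dwell_time(self) -> float:
        return sum(e.duration for e in self.events if e.kind == "dwell")


# ---------------------------------------------------------------------------


def _temperature_slots(protocol: PCRProtocol) -> list[tuple[float, ...]]:
    """Distinct temperatures grouped into per-block chains.

    Temperatures linked by a setpoint change share one block (a chain ordered
    oldest setpoint first); chains sort by their final (cycling) temperature.
    """
    temps: list[float] = []
    for t, _, _ in protocol.temperature_visits():
        if t not in temps:
            temps.append(t)
    chains: list[list[float]] = []
    chained: set[float] = set()
    for change in protocol.setpoint_changes:
        if change.from_temp not in temps or change.to_temp not in temps:
            raise ValueError(
                f"setpoint change {change.from_temp}->{change.to_temp} names "
                "temperatures the protocol never uses"
            )
        chains.append([change.from_temp, change.to_temp])
        chained |= {change.from_temp, change.to_temp}
    for t in temps:
        if t not in chained:
            chains.append([t])
    chains.sort(key=lambda c: c[-1])
    return [tuple(c) for c in chains]


def assign_blocks(protocol: PCRProtocol, layout: WheelLayout) -> BlockAssignment:
    """Assign protocol temperatures to wheel blocks in increasing-temperature order.

    If a segment is left over, it is reserved unheated for sample
    load/unload at segment 0; otherwise loading happens on the coolest
    block.  Raises if the protocol needs more simultaneous temperatures than
    the wheel has segments (suggesting a setpoint change).
    """
    slots = _temperature_slots(protocol)
    n = layout.num_segments
    if len(slots) > n:
        raise ValueError(
            f"protocol needs {len(slots)} concurrent temperatures but the wheel "
            f"has {n} segments; consider a setpoint_change to share a block"
        )
    reserve_load = len(slots) < n
    order: list[str] = []
    temp_to_block: dict[float, str] = {}
    setpoints: dict[str, float | None] = {}
    seg = 0
    if reserve_load:
        order.append("load")
        setpoints["load"] = None
        seg = 1
    for chain in slots:
        block_id = f"block{seg + 1}"
        order.append(block_id)
        setpoints[block_id] = chain[0]
        for t in chain:
            temp_to_block[t] = block_id
        seg += 1
    # pad unused segments (unheated spares)
    while len(order) < n:
        spare = f"spare{len(order)}"
        order.append(spare)
        setpoints[spare] = None
    wheel = layout.model_copy(update={"segment_order": tuple(order)})
    load_block = "load" if reserve_load else temp_to_block[min(t for c in slots for t in c)]
    return BlockAssignment(
        wheel=wheel,
        temp_to_block=temp_to_block,
        block_setpoints=setpoints,
        load_block=load_block,
    )


def compile_protocol(
    protocol: PCRProtocol,
    assignment: BlockAssignment,
    motion: MotionProfile,
) -> CompiledRun:
    """Lay the protocol out as rotations and dwells on the assigned wheel.

    The dwell clock starts at rotation completion.  Returns the full event
    timeline; ``total_duration`` spans the initial load rotation through the
    end of the final dwell (unloading excluded).
    """
    wheel = assignment.wheel
    visits = protocol.temperature_visits()
    events: list[TimelineEvent] = []
    steps: list[RotationStep] = []
    warnings: list[str] = []

    # when each setpoint change triggers (stage end times filled during walk)
    change_ready: dict[float, float] = {}  # to_temp -> earliest legal use time

    t = 0.0
    twist = 0.0
    current = assignment.load_block
    stage_of_visit: list[int] = []
    if protocol.hot_start is not None:
        stage_of_visit.append(0)
    for si, stage in enumerate(protocol.stages, start=1):
        stage_of_visit.extend([si] * (stage.cycles * len(stage.steps)))
    if protocol.final_step is not None:
        stage_of_visit.append(len(protocol.stages) + 1)

    stage_end_time: dict[int, float] = {}
    prev_stage = None
    for visit_idx, (temp, dwell, label) in enumerate(visits):
        stage_idx = stage_of_visit[visit_idx]
        if prev_stage is not None and stage_idx != prev_stage:
            stage_end_time[prev_stage] = t
            for change in protocol.setpoint_changes:
                if change.after_stage == (0 if prev_stage == 0 else prev_stage):
                    change_ready.setdefault(
                        change.to_temp, t + change.stabilization_time
                    )
        prev_stage = stage_idx

        target = assignment.temp_to_block[temp]
        if target != current:
            step = plan_rotation(current, target, wheel, twist)
            duration = transition_time(step.n_segments, motion, wheel)
            step = step.model_copy(update={"start_time": t, "duration": duration})
            steps.append(step)
            events.append(
                TimelineEvent(
                    kind="rotation",
                    label=f"{current}->{target}",
                    block=target,
                    temp=temp,
                    start=t,
                    duration=duration,
                )
            )
            twist = step.end_twist
            t += duration
            current = target
        if temp in change_ready and t < change_ready[temp]:
            warnings.append(
                f"{label}: block {target} used at {temp} degC at t={t:.1f} s, "
                f"before its setpoint change stabilizes at "
                f"t={change_ready[temp]:.1f} s"
            )
        events.append(
            TimelineEvent(
                kind="dwell",
                label=label,
                block=target,
                temp=temp,
                start=t,
                duration=dwell,
            )
        )
        t += dwell

    return CompiledRun(
        protocol_name=protocol.name,
        events=tuple(events),
        plan=RotationPlan(steps=tuple(steps)),
        total_duration=t,
        warnings=tuple(warnings),
    )


def validate(
    protocol: PCRProtocol,
    assignment: BlockAssignment,
    response: ResponseModel | None = None,
    max_adjacent_dt: float = 60.0,
) -> list[str]:
    """Static checks of a protocol/assignment pair.

    Warns when adjacent heated segments differ by more than
    ``max_adjacent_dt`` degC (the sustainable limit between neighbouring
    zones in still air) and, given a thermal response model, when any dwell
    is shorter than 3 tau (the sample cannot settle within ~5% of the step).
    """
    messages: list[str] = []
    wheel = assignment.wheel
    n = wheel.num_segments
    setpoints = assignment.block_setpoints
    for i in range(n):
        a = wheel.segment_order[i]
        b = wheel.segment_order[(i + 1) % n]
        ta, tb = setpoints.get(a), setpoints.get(b)
        if ta is None or tb is None:
            continue
        if abs(ta - tb) > max_adjacent_dt:
            messages.append(
                f"adjacent blocks {a} ({ta} degC) and {b} ({tb} degC) differ by "
                f"{abs(ta - tb):.0f} degC (> {max_adjacent_dt:.0f} degC sustainable)"
            )
    if response is not None:
        tau = response.time_constant
        for temp, dwell, label in protocol.temperature_visits():
            if dwell < 3.0 * tau:
                messages.append(
                    f"{label}: dwell {dwell:.2f} s at {temp} degC is shorter than "
                    f"3*tau = {3 * tau:.2f} s; sample will not settle within ~5%"
                )
                break  # one settle warning per protocol is enough
    return messages
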