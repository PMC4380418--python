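"""Between-run cleaning protocols as fluidic step lists with reagent budgets.

A reusable-capillary cycler must be decontaminated between runs.  The five
shipped protocols (A-E, progressively simpler to raise throughput) are
encoded as ordered :class:`FluidStep` lists with feature flags:

* ``valve_rotation_wash`` — actuate the shear valves under a bleach slug;
* ``final_inlet_flush``   — closing 500 uL water flush of the inlet;
* ``dedicated_wheel_wash`` — full / shorter / none reactor wash;
* ``inlet_wash``          — automated bleach/water washes of the sample inlet.

``reagent_totals`` sums consumption per reagent (ledger conservation);
``duration_estimate`` prices each step from a timing config (flow rates per
flow path, valve actuation time, explicit incubation/manual durations).

Volumes that the narrative does not state individually are reconstructed in
the shipped data files (marked ``reconstructed: true``); the timing config
is a calibrated fixture, both overridable.
"""

from __future__ import annotations

from typing import Literal

from pydantic import BaseModel, ConfigDict, field_validator

__all__ = [
    "FluidStep",
    "CleaningProtocol",
    "TimingConfig",
    "StepLedger",
    "reagent_totals",
    "duration_estimate",
    "diff_protocols",
]

Action = Literal["aspirate", "dispense", "flush", "incubate", "actuate_valve", "manual"]
Reagent = Literal["water", "bleach", "air", "none"]

#: actions that move liquid and are therefore priced by volume / flow rate
FLOW_ACTIONS = frozenset({"aspirate", "dispense", "flush"})


class FluidStep(BaseModel):
    """One fluidic operation, possibly repeated.

    ``consumes`` marks steps that draw fresh reagent (vs. moving a slug that
    is already counted); ``flow_path`` selects the flow rate used to price
    the step.  ``duration`` is the explicit per-repetition time for
    incubate/manual steps (flow steps are priced from volume instead).
    """

    model_config = ConfigDict(frozen=True)

    action: Action
    reagent: Reagent = "none"
    volume: float = 0.0
    duration: float = 0.0
    repetitions: int = 1
    consumes: bool = False
    flow_path: str = "wheel"
    note: str = ""

    @field_validator("volume", "duration")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("volume and duration must be non-negative")
        return v

    @field_validator("repetitions")
    @classmethod
    def _reps(cls, v: int) -> int:
        if v < 1:
            raise ValueError("repetitions must be >= 1")
        return v


class CleaningProtocol(BaseModel):
    """Ordered step list plus the feature flags of the comparison table."""

    model_config = ConfigDict(frozen=True)

    id: str
    description: str = ""
    valve_rotation_wash: bool = False
    final_inlet_flush: bool = False
    dedicated_wheel_wash: Literal["full", "shorter", "none"] = "none"
    inlet_wash: bool = False
    steps: tuple[FluidStep, ...] = ()

    def expanded_steps(self) -> list[FluidStep]:
        """Step list with repetitions unrolled."""
        out: list[FluidStep] = []
        for s in self.steps:
            out.extend([s.model_copy(update={"repetitions": 1})] * s.repetitions)
        return out


class TimingConfig(BaseModel):
    """Calibrated per-step timing: flow rates [uL/s] and fixed durations [s]."""

    model_config = ConfigDict(frozen=True)

    flow_rates: dict[str, float]
    valve_actuation_time: float = 3.0
    manual_agitation_time: float = 15.0

    @field_validator("valve_actuation_time", "manual_agitation_time")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("durations must be non-negative")
        return v


class StepLedger(BaseModel):
    """Per-reagent consumption totals [uL] and total duration [s]."""

    model_config = ConfigDict(frozen=True)

    reagent_totals_ul: dict[str, float]
    total_duration_s: float | None = None

    def total(self, reagent: str) -> float:
        return self.reagent_totals_ul.get(reagent, 0.0)


def reagent_totals(protocol: CleaningProtocol) -> StepLedger:
    """Sum consumed reagent volumes over steps x repetitions."""
    totals: dict[str, float] = {}
    for step in protocol.steps:
        if not step.consumes or step.reagent in ("air", "none"):
            continue
        totals[step.reagent] = (
            totals.get(step.reagent, 0.0) + step.volume * step.repetitions
        )
    return StepLedger(reagent_totals_ul=totals)


def duration_estimate(protocol: CleaningProtocol, timing: TimingConfig) -> float:
    """Total protocol duration [s] under a timing config.

    Flow steps cost ``volume / flow_rate(flow_path)``; incubations and
    manual steps cost their explicit duration; valve actuations cost the
    configured actuation time.  Raises if a referenced flow path has no
    configured rate, listing the missing entries.
    """
    missing = sorted(
        {
            s.flow_path
            for s in protocol.steps
            if s.action in FLOW_ACTIONS and s.flow_path not in timing.flow_rates
        }
    )
    if missing:
        raise KeyError(
            f"timing config lacks flow rates for paths: {', '.join(missing)}"
        )
    total = 0.0
    for step in protocol.steps:
        if step.action in FLOW_ACTIONS:
            per = step.volume / timing.flow_rates[step.flow_path]
        elif step.action == "actuate_valve":
            per = timing.valve_actuation_time
        else:  # incubate | manual
            per = step.duration
        total += per * step.repetitions
    return total


def diff_protocols(p1: CleaningProtocol, p2: CleaningProtocol) -> dict:
    """Structured feature/reagent/step difference between two protocols."""
    flags = {}
    for name in (
        "valve_rotation_wash",
        "final_inlet_flush",
        "dedicated_wheel_wash",
        "inlet_wash",
    ):
        a, b = getattr(p1, name), getattr(p2, name)
        if a != b:
            flags[name] = (a, b)
    l1, l2 = reagent_totals(p1), reagent_totals(p2)
    reagents = {}
    for r in sorted(set(l1.reagent_totals_ul) | set(l2.reagent_totals_ul)):
        if l1.total(r) != l2.total(r):
            reagents[r] = (l1.total(r), l2.total(r))
    n1, n2 = len(p1.expanded_steps()), len(p2.expanded_steps())
    return {
        "flags": flags,
        "reagents": reagents,
        "step_count": (n1, n2),
    }
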