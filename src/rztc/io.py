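"""File I/O: CSV temperature traces and YAML configuration files.

Trace CSV dialect: comma-separated, UTF-8, '.' decimal, required header
``time_s,temp_C``, '#' comment lines.  Config files are YAML mappings with a
``schema_version`` field; human units at the file boundary (um for
diameters, g for block mass, uL for volumes) are converted to SI on read.

Packaged defaults live under ``rztc/data``: a cycler definition, the three
shipped PCR protocols, the five cleaning protocols, and the calibrated
cleaning timing config.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd
import yaml

from .cleaning import CleaningProtocol, FluidStep, TimingConfig
from .fixtures import SCHEMA_VERSION, CyclerConfig
from .kinematics import MotionProfile, WheelLayout
from .protocol import (
    PCRProtocol,
    ProtocolStage,
    ProtocolStep,
    SetpointChange,
)
from .thermal import DEFAULT_MATERIALS, CapillarySpec, HeaterBlockSpec, Material
from .traces import TemperatureTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_config",
    "default_config",
    "read_protocol",
    "packaged_protocol",
    "read_cleaning_protocol",
    "packaged_cleaning_protocols",
    "read_timing",
    "default_timing",
]

TRACE_COLUMNS = ("time_s", "temp_C")


# ---------------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------------


def read_trace(path: str | Path) -> TemperatureTrace:
    """Read a two-column temperature log; informative errors on bad input."""
    path = Path(path)
    try:
        df = pd.read_csv(path, comment="#")
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trace file") from None
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing required column(s) {', '.join(missing)} "
            f"(found: {', '.join(map(str, df.columns))})"
        )
    t = df["time_s"].to_numpy(dtype=float)
    y = df["temp_C"].to_numpy(dtype=float)
    bad = [i for i in range(len(t)) if not (pd.notna(t[i]) and pd.notna(y[i]))]
    if bad:
        # +2: one for the header, one for 1-based numbering
        raise ValueError(f"{path}: non-numeric value at line {bad[0] + 2}")
    dt = pd.Series(t).diff().median()
    rate = 1.0 / float(dt) if dt and dt > 0 else 10.0
    return TemperatureTrace(times=t, temperatures=y, sampling_rate=rate)


def write_trace(trace: TemperatureTrace, path: str | Path, comment: str = "") -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(",".join(TRACE_COLUMNS) + "\n")
        for t, y in zip(trace.times, trace.temperatures):
            fh.write(f"{t:.6g},{y:.6g}\n")


# ---------------------------------------------------------------------------
# YAML helpers
# ---------------------------------------------------------------------------


def _load_yaml(source: str | Path | dict) -> dict:
    if isinstance(source, dict):
        return source
    path = Path(source)
    with path.open("r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: expected a YAML mapping at top level")
    return data


def _check_schema(data: dict, what: str) -> None:
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"{what}: schema_version {version!r} unsupported "
            f"(expected {SCHEMA_VERSION})"
        )


def _packaged(relpath: str) -> dict:
    ref = resources.files("rztc").joinpath("data", relpath)
    data = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return data


# ---------------------------------------------------------------------------
# cycler configuration
# ---------------------------------------------------------------------------


def _build_config(data: dict) -> CyclerConfig:
    _check_schema(data, "cycler config")
    materials = dict(DEFAULT_MATERIALS)
    for name, props in (data.get("materials") or {}).items():
        materials[name] = Material(name=name, **props)

    def mat(name: str) -> Material:
        if name not in materials:
            raise ValueError(f"cycler config references unknown material {name!r}")
        return materials[name]

    cap = data["capillary"]
    capillary = CapillarySpec(
        inner_diameter=cap["inner_diameter_um"] * 1e-6,
        outer_diameter=cap["outer_diameter_um"] * 1e-6,
        wall_material=mat(cap["wall_material"]),
    )
    blocks = tuple(
        HeaterBlockSpec(
            id=b["id"],
            mass=b["mass_g"] * 1e-3,
            material=mat(b["material"]),
            setpoint=b.get("setpoint"),
            arc_span=b.get("arc_span", data["layout"].get("arc_span", 73.6)),
        )
        for b in data["blocks"]
    )
    layout = WheelLayout(**data["layout"])
    motion = MotionProfile(**data.get("motion", {}))
    return CyclerConfig(
        schema_version=data["schema_version"],
        name=data.get("name", "cycler"),
        materials=materials,
        capillary=capillary,
        blocks=blocks,
        layout=layout,
        motion=motion,
        sample_volume_ul=data.get("sample_volume_ul", 4.0),
    )


def read_config(path: str | Path) -> CyclerConfig:
    return _build_config(_load_yaml(path))


def default_config() -> CyclerConfig:
    """The shipped four-segment reference cycler."""
    return _build_config(_packaged("cycler_default.yaml"))


# ---------------------------------------------------------------------------
# PCR protocols
# ---------------------------------------------------------------------------


def _build_protocol(data: dict) -> PCRProtocol:
    _check_schema(data, "protocol")

    def step(d: dict, dwell_key: str = "dwell") -> ProtocolStep:
        return ProtocolStep(
            temp=d["temp"], dwell=d[dwell_key], label=d.get("label", "")
        )

    stages = tuple(
        ProtocolStage(
            cycles=s["cycles"], steps=tuple(step(x) for x in s["steps"])
        )
        for s in data.get("stages", [])
    )
    changes = tuple(
        SetpointChange(**c) for c in data.get("setpoint_changes", [])
    )
    return PCRProtocol(
        name=data.get("name", ""),
        hot_start=step(data["hot_start"], "duration") if "hot_start" in data else None,
        stages=stages,
        final_step=step(data["final_step"], "duration")
        if "final_step" in data
        else None,
        setpoint_changes=changes,
    )


def read_protocol(path: str | Path) -> PCRProtocol:
    return _build_protocol(_load_yaml(path))


def packaged_protocol(name: str) -> PCRProtocol:
    """Load a shipped protocol: 'phusion', 'powerplex' or 'cdna'."""
    return _build_protocol(_packaged(f"protocols/{name}.yaml"))


# ---------------------------------------------------------------------------
# cleaning protocols & timing
# ---------------------------------------------------------------------------


def _build_cleaning(data: dict) -> CleaningProtocol:
    _check_schema(data, "cleaning protocol")
    steps = tuple(FluidStep(**s) for s in data["steps"])
    return CleaningProtocol(
        id=data["id"],
        description=data.get("description", ""),
        valve_rotation_wash=data.get("valve_rotation_wash", False),
        final_inlet_flush=data.get("final_inlet_flush", False),
        dedicated_wheel_wash=data.get("dedicated_wheel_wash", "none"),
        inlet_wash=data.get("inlet_wash", False),
        steps=steps,
    )


def read_cleaning_protocol(path: str | Path) -> CleaningProtocol:
    return _build_cleaning(_load_yaml(path))


def packaged_cleaning_protocols() -> dict[str, CleaningProtocol]:
    """The five shipped protocols keyed 'A'..'E'."""
    out = {}
    for pid in "ABCDE":
        out[pid] = _build_cleaning(_packaged(f"cleaning/protocol_{pid.lower()}.yaml"))
    return out


def read_timing(path: str | Path) -> TimingConfig:
    data = _load_yaml(path)
    _check_schema(data, "timing config")
    data = {k: v for k, v in data.items() if k != "schema_version"}
    return TimingConfig(**data)


def default_timing() -> TimingConfig:
    data = _packaged("timing_default.yaml")
    data = {k: v for k, v in data.items() if k != "schema_version"}
    return TimingConfig(**data)
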