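"""Lumped-capacitance thermal network primitives for a spatial thermal cycler.

A rotary-zone cycler holds the sample in a thin-walled capillary that is
pressed against a sequence of constant-temperature heater blocks.  The
sample + capillary wall are treated as a single isothermal lump exchanging
heat with the engaged block through the conductive resistance of the
capillary wall (contact resistance is neglected by default).  This module
derives the network elements from geometry and material properties:

* ``wall_resistance``   — half-cylinder radial conductive resistance,
  ``R = ln(d_o/d_i) / (pi * L * k)``  [K/W]
* ``lump_capacitance``  — sample + wall capacitance per engaged length,
  ``C = L * (pi/4) * [rho_s c_s d_i^2 + rho_c c_c (d_o^2 - d_i^2)]``  [J/K]
* ``predict_time_constant`` — the a-priori first-order time constant
  ``tau = R * C`` (independent of engaged length, which cancels)
* ``equilibrium_temperature`` — two-lump energy balance for a finite block

All temperatures are degrees Celsius, lengths metres, times seconds.
"""

from __future__ import annotations

import math

from pydantic import BaseModel, ConfigDict, field_validator, model_validator

__all__ = [
    "Material",
    "DEFAULT_MATERIALS",
    "CapillarySpec",
    "BoreContents",
    "EngagementGeometry",
    "HeaterBlockSpec",
    "ThermalLump",
    "ResponseModel",
    "wall_resistance",
    "lump_capacitance",
    "block_capacitance",
    "predict_time_constant",
    "equilibrium_temperature",
]


class Material(BaseModel):
    """Thermophysical properties of a solid or liquid.

    ``thermal_conductivity`` [W/(m K)], ``density`` [kg/m^3] and
    ``specific_heat`` [J/(kg K)] must all be positive.  Conductivity is
    only consulted for capillary-wall materials; capacitance calculations
    use only ``density * specific_heat``.
    """

    model_config = ConfigDict(frozen=True)

    name: str
    thermal_conductivity: float
    density: float
    specific_heat: float

    @field_validator("thermal_conductivity", "density", "specific_heat")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("material properties must be positive")
        return v

    @property
    def volumetric_heat_capacity(self) -> float:
        """rho * c_P in J/(m^3 K)."""
        return self.density * self.specific_heat


#: Handbook property table used by the shipped configs.  Overridable via the
#: materials section of a cycler config file.
DEFAULT_MATERIALS: dict[str, Material] = {
    "water": Material(
        name="water", thermal_conductivity=0.606, density=997.0, specific_heat=4181.0
    ),
    "fep": Material(
        name="fep", thermal_conductivity=0.195, density=2150.0, specific_heat=1172.0
    ),
    "polycarbonate": Material(
        name="polycarbonate",
        thermal_conductivity=0.20,
        density=1200.0,
        specific_heat=1200.0,
    ),
    "aluminum": Material(
        name="aluminum", thermal_conductivity=205.0, density=2700.0, specific_heat=897.0
    ),
    "thermocouple": Material(
        # K-type wire, chromel/alumel average
        name="thermocouple",
        thermal_conductivity=25.0,
        density=8700.0,
        specific_heat=450.0,
    ),
}


class CapillarySpec(BaseModel):
    """Sample capillary geometry: inner/outer diameter [m] and wall material."""

    model_config = ConfigDict(frozen=True)

    inner_diameter: float
    outer_diameter: float
    wall_material: Material

    @model_validator(mode="after")
    def _check_diameters(self) -> "CapillarySpec":
        if not (0 < self.inner_diameter < self.outer_diameter):
            raise ValueError("require 0 < inner_diameter < outer_diameter")
        return self


class BoreContents(BaseModel):
    """What fills the capillary bore.

    By default the bore is full of sample (water).  ``inclusions`` lists
    cylindrical objects running along the bore — e.g. the two legs of a fine
    thermocouple — each displacing its own cross-section of sample.
    """

    sample_material: Material = DEFAULT_MATERIALS["water"]
    inclusions: tuple[tuple[float, Material], ...] = ()

    model_config = ConfigDict(frozen=True)

    def inclusion_d2(self) -> float:
        """Sum of inclusion diameters squared (the pi/4 factor is applied later)."""
        return sum(d * d for d, _ in self.inclusions)

    def validate_against(self, cap: CapillarySpec) -> None:
        if self.inclusion_d2() >= cap.inner_diameter**2:
            raise ValueError("inclusion cross-section exceeds bore cross-section")


class EngagementGeometry(BaseModel):
    """Length of capillary held against the heater block [m]."""

    model_config = ConfigDict(frozen=True)

    contact_length: float

    @field_validator("contact_length")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("contact_length must be positive")
        return v


class HeaterBlockSpec(BaseModel):
    """One wheel segment: a machined metal block acting as a thermal reservoir.

    ``setpoint`` is the controlled block temperature in deg C; ``None`` marks an
    unheated segment (used for sample load/unload).  ``arc_span`` is the angular
    extent of the block face in degrees.
    """

    model_config = ConfigDict(frozen=True)

    id: str
    mass: float
    material: Material
    setpoint: float | None = None
    arc_span: float = 73.6

    @field_validator("mass")
    @classmethod
    def _positive_mass(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("mass must be positive")
        return v

    @field_validator("arc_span")
    @classmethod
    def _arc(cls, v: float) -> float:
        if not (0 < v <= 360):
            raise ValueError("arc_span must lie in (0, 360]")
        return v


class ThermalLump(BaseModel):
    """An isothermal node with heat capacitance ``capacitance`` [J/K]."""

    model_config = ConfigDict(frozen=True)

    capacitance: float
    label: str = ""

    @field_validator("capacitance")
    @classmethod
    def _nonneg(cls, v: float) -> float:
        if v < 0:
            raise ValueError("capacitance must be non-negative")
        return v


class ResponseModel(BaseModel):
    """First-order bounded-exponential response: T(t) = T_B + (T0-T_B) e^{-(t-t0)/tau}.

    ``time_constant`` (tau, s) is the 70.7% rise/fall time; ``offset`` (t0, s)
    shifts the response origin (absorbs trigger/rotation latency in fits).
    An optional asymmetric pair may be carried for heating vs cooling.
    """

    model_config = ConfigDict(frozen=True)

    time_constant: float
    offset: float = 0.0
    cooling_time_constant: float | None = None

    @field_validator("time_constant")
    @classmethod
    def _positive(cls, v: float) -> float:
        if v <= 0:
            raise ValueError("time_constant must be positive")
        return v

    def tau_for(self, heating: bool) -> float:
        if not heating and self.cooling_time_constant is not None:
            return self.cooling_time_constant
        return self.time_constant


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def wall_resistance(
    cap: CapillarySpec,
    eng: EngagementGeometry,
    contact_resistance: float = 0.0,
) -> float:
    """Conductive resistance of the engaged half-cylinder capillary wall [K/W].

    ``R = ln(d_o / d_i) / (pi * L * k)`` with an optional additive series
    ``contact_resistance`` between tube and block (default 0: the tube is
    assumed tensioned firmly into its groove).
    """
    if contact_resistance < 0:
        raise ValueError("contact_resistance must be non-negative")
    k = cap.wall_material.thermal_conductivity
    r = math.log(cap.outer_diameter / cap.inner_diameter) / (
        math.pi * eng.contact_length * k
    )
    return r + contact_resistance


def lump_capacitance(
    cap: CapillarySpec,
    contents: BoreContents,
    eng: EngagementGeometry,
    label: str = "sample+capillary",
) -> ThermalLump:
    """Heat capacitance of the engaged sample + capillary wall [J/K].

    ``C = L * (pi/4) * [rho_s c_s d_i^2 + rho_c c_c (d_o^2 - d_i^2)]``, with
    each bore inclusion substituting its own ``rho c_P`` for the sample it
    displaces.
    """
    contents.validate_against(cap)
    di2 = cap.inner_diameter**2
    do2 = cap.outer_diameter**2
    incl_d2 = contents.inclusion_d2()
    per_area = contents.sample_material.volumetric_heat_capacity * (di2 - incl_d2)
    per_area += sum(d * d * m.volumetric_heat_capacity for d, m in contents.inclusions)
    per_area += cap.wall_material.volumetric_heat_capacity * (do2 - di2)
    c = eng.contact_length * math.pi / 4.0 * per_area
    return ThermalLump(capacitance=c, label=label)


def block_capacitance(block: HeaterBlockSpec) -> ThermalLump:
    """Block heat capacitance C_B = mass * c_P [J/K]."""
    return ThermalLump(
        capacitance=block.mass * block.material.specific_heat,
        label=f"block:{block.id}",
    )


def predict_time_constant(
    cap: CapillarySpec,
    contents: BoreContents | None = None,
    contact_resistance_per_length: float = 0.0,
) -> ResponseModel:
    """A-priori time constant tau = R*C of the engaged sample capillary.

    The engaged length cancels between resistance (~1/L) and capacitance
    (~L), so tau depends only on diameters and material properties; a unit
    length is used internally.  ``contact_resistance_per_length`` is an
    optional series term in K.m/W referenced to the same unit length.
    """
    contents = contents if contents is not None else BoreContents()
    eng = EngagementGeometry(contact_length=1.0)
    r = wall_resistance(cap, eng, contact_resistance=contact_resistance_per_length)
    c = lump_capacitance(cap, contents, eng).capacitance
    return ResponseModel(time_constant=r * c, offset=0.0)


def equilibrium_temperature(
    block_temp: float,
    sample_temp: float,
    sample: ThermalLump,
    block: ThermalLump,
) -> float:
    """Passive two-lump equilibrium after a block engages the capillary [degC].

    With the heater off, the engaged block (capacitance C_B at ``block_temp``)
    and the sample lump (C_SC at ``sample_temp``) relax to

        T_eq = (T_B + T_SC * (C_SC/C_B)) / (1 + C_SC/C_B)

    which tends to T_B as C_SC/C_B -> 0.  The result is a convex combination
    of the two temperatures (energy conservation).
    """
    if block.capacitance <= 0:
        raise ValueError("block capacitance must be positive")
    ratio = sample.capacitance / block.capacitance
    return (block_temp + sample_temp * ratio) / (1.0 + ratio)
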