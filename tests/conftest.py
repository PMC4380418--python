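import pytest

from rztc import (
    BoreContents,
    CapillarySpec,
    DEFAULT_MATERIALS,
    HeaterBlockSpec,
    MotionProfile,
    WheelLayout,
    calibrate_steps_per_segment,
    default_config,
)


@pytest.fixture(scope="session")
def motion() -> MotionProfile:
    return MotionProfile(acceleration=6103.52, max_velocity=4000.0)


@pytest.fixture(scope="session")
def layout(motion) -> WheelLayout:
    """Four-segment wheel calibrated so a 1-segment move takes 1.32 s."""
    steps = calibrate_steps_per_segment(1.32, motion)
    return WheelLayout(steps_per_segment=steps)


@pytest.fixture(scope="session")
def fep_capillary() -> CapillarySpec:
    return CapillarySpec(
        inner_diameter=406e-6,
        outer_diameter=794e-6,
        wall_material=DEFAULT_MATERIALS["fep"],
    )


@pytest.fixture(scope="session")
def pc_capillary() -> CapillarySpec:
    return CapillarySpec(
        inner_diameter=562e-6,
        outer_diameter=750e-6,
        wall_material=DEFAULT_MATERIALS["polycarbonate"],
    )


@pytest.fixture(scope="session")
def thermocouple_contents() -> BoreContents:
    """Water bore with the two 50 um legs of a fine thermocouple."""
    wire = DEFAULT_MATERIALS["thermocouple"]
    return BoreContents(inclusions=((50e-6, wire), (50e-6, wire)))


@pytest.fixture(scope="session")
def aluminum_block() -> HeaterBlockSpec:
    return HeaterBlockSpec(
        id="b", mass=0.055, material=DEFAULT_MATERIALS["aluminum"], setpoint=98.0
    )


@pytest.fixture(scope="session")
def reference_config():
    return default_config()
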