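"""Thermal network primitives: resistances, capacitances, tau, equilibria."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rztc import (
    BoreContents,
    CapillarySpec,
    DEFAULT_MATERIALS,
    EngagementGeometry,
    HeaterBlockSpec,
    ThermalLump,
    block_capacitance,
    equilibrium_temperature,
    lump_capacitance,
    predict_time_constant,
    wall_resistance,
)

WATER = DEFAULT_MATERIALS["water"]
FEP = DEFAULT_MATERIALS["fep"]
AL = DEFAULT_MATERIALS["aluminum"]
L1 = EngagementGeometry(contact_length=1.0)


class TestWallResistance:
    def test_fep_per_meter(self, fep_capillary):
        # hand evaluation: ln(794/406)/(pi * 0.195) = 1.0949 K.m/W
        assert wall_resistance(fep_capillary, L1) == pytest.approx(1.0949, rel=1e-3)

    def test_equal_diameters_degenerate_gives_zero(self):
        # bypass the d_o > d_i invariant to check the ln(1) = 0 limit
        cap = CapillarySpec.model_construct(
            inner_diameter=500e-6, outer_diameter=500e-6, wall_material=FEP
        )
        assert wall_resistance(cap, L1) == 0.0

    def test_inverse_length_scaling(self, fep_capillary):
        r1 = wall_resistance(fep_capillary, EngagementGeometry(contact_length=0.02))
        r2 = wall_resistance(fep_capillary, EngagementGeometry(contact_length=0.04))
        assert r1 == pytest.approx(2.0 * r2)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            CapillarySpec(
                inner_diameter=800e-6, outer_diameter=500e-6, wall_material=FEP
            )
        with pytest.raises(ValueError):
            EngagementGeometry(contact_length=0.0)

    @given(ratio=st.floats(min_value=1.01, max_value=20.0))
    @settings(derandomize=True, max_examples=50)
    def test_monotone_in_diameter_ratio(self, ratio):
        di = 400e-6
        r_lo = wall_resistance(
            CapillarySpec(
                inner_diameter=di, outer_diameter=di * ratio, wall_material=FEP
            ),
            L1,
        )
        r_hi = wall_resistance(
            CapillarySpec(
                inner_diameter=di, outer_diameter=di * ratio * 1.1, wall_material=FEP
            ),
            L1,
        )
        assert r_hi > r_lo

    def test_contact_resistance_adds_in_series(self, fep_capillary):
        base = wall_resistance(fep_capillary, L1)
        assert wall_resistance(fep_capillary, L1, contact_resistance=0.5) == (
            pytest.approx(base + 0.5)
        )


class TestLumpCapacitance:
    def test_fep_water_per_meter(self, fep_capillary):
        # hand evaluation of (pi/4)[rho_w c_w d_i^2 + rho_c c_c (d_o^2-d_i^2)]
        c = lump_capacitance(fep_capillary, BoreContents(), L1)
        assert c.capacitance == pytest.approx(1.4611, rel=1e-3)

    def test_zero_length_degenerate(self, fep_capillary):
        eng = EngagementGeometry.model_construct(contact_length=0.0)
        assert lump_capacitance(fep_capillary, BoreContents(), eng).capacitance == 0.0

    def test_linear_in_length(self, fep_capillary):
        c1 = lump_capacitance(
            fep_capillary, BoreContents(), EngagementGeometry(contact_length=0.01)
        )
        c2 = lump_capacitance(
            fep_capillary, BoreContents(), EngagementGeometry(contact_length=0.03)
        )
        assert c2.capacitance == pytest.approx(3.0 * c1.capacitance)

    def test_additive_over_inclusions(self, pc_capillary, thermocouple_contents):
        """Swapping bore water for wire changes C by the rho*c_P difference."""
        plain = lump_capacitance(pc_capillary, BoreContents(), L1).capacitance
        with_tc = lump_capacitance(pc_capillary, thermocouple_contents, L1).capacitance
        wire = DEFAULT_MATERIALS["thermocouple"]
        d2 = 2 * (50e-6) ** 2
        expected_delta = (
            math.pi
            / 4.0
            * d2
            * (wire.volumetric_heat_capacity - WATER.volumetric_heat_capacity)
        )
        assert with_tc - plain == pytest.approx(expected_delta, rel=1e-12)

    def test_inclusion_overflow_rejected(self, pc_capillary):
        wire = DEFAULT_MATERIALS["thermocouple"]
        too_big = BoreContents(inclusions=((600e-6, wire),))
        with pytest.raises(ValueError):
            lump_capacitance(pc_capillary, too_big, L1)


class TestBlockCapacitance:
    def test_reference_55g_aluminum(self, aluminum_block):
        assert block_capacitance(aluminum_block).capacitance == pytest.approx(
            49.3, rel=5e-3
        )

    def test_linearity_in_mass(self, aluminum_block):
        double = aluminum_block.model_copy(update={"mass": 0.110})
        assert block_capacitance(double).capacitance == pytest.approx(
            2.0 * block_capacitance(aluminum_block).capacitance
        )

    def test_zero_mass_rejected(self):
        with pytest.raises(ValueError):
            HeaterBlockSpec(id="z", mass=0.0, material=AL)


class TestTimeConstant:
    def test_fep_water(self, fep_capillary):
        tau = predict_time_constant(fep_capillary).time_constant
        assert tau == pytest.approx(1.6, rel=0.05)

    def test_pc_with_thermocouple(self, pc_capillary, thermocouple_contents):
        tau = predict_time_constant(pc_capillary, thermocouple_contents).time_constant
        assert tau == pytest.approx(0.590, rel=0.05)

    def test_length_cancels(self, fep_capillary):
        """tau = R(L) * C(L) is identical across four decades of L."""
        taus = []
        for length in (1e-3, 1e-2, 1e-1, 1.0):
            eng = EngagementGeometry(contact_length=length)
            r = wall_resistance(fep_capillary, eng)
            c = lump_capacitance(fep_capillary, BoreContents(), eng).capacitance
            taus.append(r * c)
        for tau in taus[1:]:
            assert tau == pytest.approx(taus[0], rel=1e-12)
        assert predict_time_constant(fep_capillary).time_constant == pytest.approx(
            taus[0], rel=1e-12
        )

    def test_matches_term_by_term_oracle(self, pc_capillary, thermocouple_contents):
        """Independent numeric evaluation of R and C term by term."""
        di, do = 562e-6, 750e-6
        k = pc_capillary.wall_material.thermal_conductivity
        r = math.log(do / di) / (math.pi * 1.0 * k)
        wire = DEFAULT_MATERIALS["thermocouple"]
        d2 = 2 * (50e-6) ** 2
        c = (math.pi / 4.0) * (
            WATER.density * WATER.specific_heat * (di**2 - d2)
            + wire.density * wire.specific_heat * d2
            + pc_capillary.wall_material.density
            * pc_capillary.wall_material.specific_heat
            * (do**2 - di**2)
        )
        tau = predict_time_constant(pc_capillary, thermocouple_contents).time_constant
        assert tau == pytest.approx(r * c, rel=1e-12)


class TestEquilibriumTemperature:
    def test_massive_block_limit(self):
        sample = ThermalLump(capacitance=0.0)
        block = ThermalLump(capacitance=49.3)
        assert equilibrium_temperature(96.0, 60.0, sample, block) == 96.0

    def test_equal_capacitance_midpoint(self):
        lump = ThermalLump(capacitance=1.0)
        assert equilibrium_temperature(96.0, 60.0, lump, lump) == pytest.approx(78.0)

    def test_energy_balance_oracle(self, reference_config):
        """4 uL engaged water+FEP vs a 55 g block: conserve total enthalpy."""
        cfg = reference_config
        sample = lump_capacitance(
            cfg.capillary, cfg.bore_contents(), cfg.engagement()
        )
        block = block_capacitance(cfg.block("denature"))
        t_eq = equilibrium_temperature(96.0, 60.0, sample, block)
        oracle = (block.capacitance * 96.0 + sample.capacitance * 60.0) / (
            block.capacitance + sample.capacitance
        )
        assert t_eq == pytest.approx(oracle, rel=1e-12)
        # the small sample barely perturbs the block
        assert 95.9 < t_eq < 96.0

    @given(
        tb=st.floats(min_value=-20, max_value=120),
        tsc=st.floats(min_value=-20, max_value=120),
        ratio=st.floats(min_value=0.0, max_value=10.0),
    )
    @settings(derandomize=True, max_examples=100)
    def test_convex_combination(self, tb, tsc, ratio):
        sample = ThermalLump(capacitance=ratio)
        block = ThermalLump(capacitance=1.0)
        t_eq = equilibrium_temperature(tb, tsc, sample, block)
        lo, hi = min(tb, tsc), max(tb, tsc)
        assert lo - 1e-9 <= t_eq <= hi + 1e-9
        # weights sum to one
        w_b = 1.0 / (1.0 + ratio)
        assert t_eq == pytest.approx(w_b * tb + (1 - w_b) * tsc, abs=1e-9)

    def test_zero_block_capacitance_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_temperature(
                96.0, 60.0, ThermalLump(capacitance=1.0), ThermalLump(capacitance=0.0)
            )
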