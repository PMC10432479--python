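import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tenposim.device_model import (DeviceGeometry, FlowCondition,
                                   InvalidGeometryError,
                                   canonical_pore_density, mean_pore_velocity,
                                   occlusion_flow_multiplier, pore_count,
                                   pore_hydraulic_resistance)
from tenposim.units import UnitError, parse_quantity

ML_PER_H = 1e-6 / 3600.0


class TestPoreCount:
    def test_reference_membrane(self):
        # 2.12e6 pores/cm² over 2.5 cm² is the 5.3-million-pore device
        g = DeviceGeometry(pore_diameter=3e-6, pore_density=2.12e6 * 1e4,
                           membrane_area=2.5e-4)
        assert pore_count(g) == 5_300_000

    def test_unit_area(self):
        g = DeviceGeometry(pore_diameter=3e-6, pore_density=1e6 * 1e4,
                           membrane_area=1e-4)
        assert pore_count(g) == 1_000_000

    def test_empty_device_rejected(self):
        with pytest.raises(InvalidGeometryError):
            DeviceGeometry(pore_diameter=3e-6, pore_density=1e10,
                           membrane_area=0.0)

    def test_overlapping_pores_rejected(self):
        with pytest.raises(InvalidGeometryError):
            DeviceGeometry(pore_diameter=12e-6, pore_density=1e12)


class TestMeanPoreVelocity:
    def test_reference_value(self, geo3, flow25):
        # ɸ/(N·a_pore) for the 3 µm reference device at 2.5 mL/h
        assert mean_pore_velocity(geo3, flow25) == pytest.approx(1.85e-5,
                                                                 rel=0.01)

    def test_no_flow(self, geo3):
        assert mean_pore_velocity(geo3, FlowCondition(0.0)) == 0.0

    def test_linear_in_flow_rate(self, geo3, flow25):
        doubled = FlowCondition(2 * flow25.volumetric_flow_rate)
        assert mean_pore_velocity(geo3, doubled) == pytest.approx(
            2 * mean_pore_velocity(geo3, flow25))

    def test_constant_velocity_densities(self):
        # canonical densities keep Vz constant across diameters
        fl = FlowCondition(2.5 * ML_PER_H)
        v = [mean_pore_velocity(DeviceGeometry(d), fl)
             for d in (0.6e-6, 1e-6, 3e-6, 12e-6)]
        assert np.allclose(v, v[0], rtol=1e-9)
        assert canonical_pore_density(3e-6) == pytest.approx(2.12e10)


class TestHydraulicResistance:
    def test_zero_length_is_orifice_term(self):
        g = DeviceGeometry(pore_diameter=3e-6, nife_thickness=1e-15,
                           backing_thickness=1e-15)
        r = g.pore_radius
        assert pore_hydraulic_resistance(g) == pytest.approx(3e-3 / r**3,
                                                             rel=1e-6)

    def test_channel_term_r4_scaling(self):
        mu, L = 1e-3, 5.2e-6
        chan = lambda r: 8 * mu * L / (math.pi * r**4)
        assert chan(0.75e-6) / chan(1.5e-6) == pytest.approx(16.0)

    def test_strictly_decreasing_in_radius(self):
        vals = [pore_hydraulic_resistance(DeviceGeometry(d))
                for d in (1e-6, 2e-6, 3e-6, 6e-6, 12e-6)]
        assert all(a > b for a, b in zip(vals, vals[1:]))


class TestOcclusion:
    @pytest.mark.parametrize("n, k, expected", [
        (9, 0, 1.0),
        (9, 4, 1.8),    # the ~80 % redistribution increase
        (9, 1, 1.125),  # mass conservation over 8 open pores
    ])
    def test_multiplier(self, n, k, expected):
        assert occlusion_flow_multiplier(n, k) == pytest.approx(expected)

    def test_all_occluded_is_error(self):
        with pytest.raises(InvalidGeometryError):
            occlusion_flow_multiplier(9, 9)

    @given(st.integers(2, 50), st.integers(0, 48))
    def test_flux_conserved_and_monotone(self, n, k):
        if k >= n:
            return
        mult = occlusion_flow_multiplier(n, k)
        # open pores carry exactly the total flux
        assert (n - k) * mult == pytest.approx(n)
        if k + 1 < n:
            assert occlusion_flow_multiplier(n, k + 1) > mult


class TestUnits:
    @pytest.mark.parametrize("text, si", [
        ("2.5 mL/h", 2.5e-6 / 3600),
        ("3 um", 3e-6),
        ("200 nm", 2e-7),
        ("2.5 cm^2", 2.5e-4),
        ("0.4 T", 0.4),
        ("1 mPa.s", 1e-3),
        ("341000 A/m", 341000.0),
        ("2.12e6 1/cm^2", 2.12e10),
    ])
    def test_parse(self, text, si):
        assert parse_quantity(text) == pytest.approx(si)

    def test_unknown_unit(self):
        with pytest.raises(UnitError):
            parse_quantity("3 furlongs")
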