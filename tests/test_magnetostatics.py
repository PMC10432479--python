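import math

import numpy as np
import pytest

from tenposim.device_model import DeviceGeometry
from tenposim.magnetostatics import (MU0, FieldTable, MagneticEnvironment,
                                     NIFE_SATURATION, PoreField,
                                     PositionInFilmError,
                                     demag_limited_magnetization,
                                     disk_axial_field, magnetized_disk_field)


@pytest.fixture(scope="module")
def env():
    return MagneticEnvironment()


@pytest.fixture(scope="module")
def pf3(env):
    return PoreField(env, DeviceGeometry(3e-6))


class TestDiskAxialField:
    def test_unmagnetized(self):
        z = np.linspace(-1e-6, 1e-6, 7)
        assert np.allclose(disk_axial_field(0.0, 1.5e-6, 2e-7, z), 0.0)

    def test_dipole_far_field(self):
        # |z|⁻³ decay: Bz(2z)/Bz(z) → 1/8
        b1 = disk_axial_field(NIFE_SATURATION, 1.5e-6, 2e-7, 200e-6)
        b2 = disk_axial_field(NIFE_SATURATION, 1.5e-6, 2e-7, 400e-6)
        assert b1 / b2 == pytest.approx(8.0, rel=1e-3)
        assert np.allclose(disk_axial_field(NIFE_SATURATION, 1.5e-6, 2e-7,
                                            np.array([-0.5e-6, 0.5e-6])),
                           disk_axial_field(NIFE_SATURATION, 1.5e-6, 2e-7,
                                            np.array([0.5e-6, 0.5e-6])))

    def test_matches_solenoid_quadrature(self):
        # independent oracle: equivalent-current quadrature on the axis
        ms, R, t = 6.29e5, 1.5e-6, 200e-9
        for z in [0.5e-6, 50e-9, -100e-9, 3e-6]:
            _, bz = magnetized_disk_field(0.0, z, R, t, ms)
            bz_cf = disk_axial_field(ms, R, t, z + t / 2)
            assert float(bz) == pytest.approx(float(bz_cf), rel=1e-6)


class TestPoreField:
    def test_far_field_is_external(self, pf3, env):
        b = pf3.pore_field([0.0, 0.0, 60e-6])
        assert np.allclose(b, [0, 0, env.b_external], atol=1e-6)

    def test_unmagnetized_film_uniform(self):
        pf = PoreField(MagneticEnvironment(film_saturation=0.0),
                       DeviceGeometry(3e-6))
        for pos in ([0, 0, 1e-6], [1e-6, 0.5e-6, -0.1e-6], [2e-6, 0, 0.05e-6]):
            assert np.allclose(pf.pore_field(pos), [0, 0, 0.4])

    def test_babinet_on_axis_identity(self, pf3, env):
        # on-axis total field equals B_ext minus the magnetized-disk field
        g = pf3.geometry
        for z in [1e-6, 0.3e-6, -0.1e-6]:
            _, bz = pf3.b_cyl(0.0, z)
            disk = disk_axial_field(env.film_saturation, g.pore_radius,
                                    g.nife_thickness,
                                    z + g.nife_thickness / 2)
            assert float(bz) == pytest.approx(env.b_external - float(disk),
                                              rel=1e-6)

    def test_axisymmetric(self, pf3):
        rho, z = 1.1e-6, 0.2e-6
        vals = []
        for theta in [0.0, 0.7, 2.1, 4.0]:
            b = pf3.pore_field([rho * math.cos(theta), rho * math.sin(theta), z])
            vals.append([math.hypot(b[0], b[1]), b[2]])
        assert np.allclose(vals, vals[0], rtol=1e-12, atol=1e-15)

    def test_error_inside_film(self, pf3):
        with pytest.raises(PositionInFilmError):
            pf3.pore_field([2e-6, 0.0, -100e-9])

    def test_divergence_free(self, pf3):
        # numerical ∇·B below 1e-3 · |B|/d at sampled fluid points
        d = pf3.geometry.pore_diameter
        h = 0.5e-9
        for rho, z in [(0.5e-6, 0.2e-6), (1.4e-6, 0.1e-6), (1.7e-6, 0.05e-6),
                       (1.0e-6, -0.1e-6)]:
            br_p, _ = pf3.b_cyl(rho + h, z, check=False)
            br_m, _ = pf3.b_cyl(rho - h, z, check=False)
            br, bz = pf3.b_cyl(rho, z, check=False)
            _, bz_p = pf3.b_cyl(rho, z + h, check=False)
            _, bz_m = pf3.b_cyl(rho, z - h, check=False)
            div = ((br_p - br_m) / (2 * h) + br / rho
                   + (bz_p - bz_m) / (2 * h))
            bmag = math.hypot(float(br), float(bz))
            assert abs(div) < 1e-3 * bmag / d

    @pytest.mark.parametrize("d", [0.6e-6, 1e-6, 3e-6, 12e-6])
    def test_trap_at_pore_edge(self, env, d):
        # |B| along the membrane surface peaks at the pore edge for every d
        g = DeviceGeometry(d)
        pf = PoreField(env, g)
        rho = np.linspace(0.2 * g.pore_radius, g.unit_cell_radius, 1500)
        b2 = pf.b_squared(rho, np.full_like(rho, 5e-9), check=False)
        peak = rho[np.argmax(b2)]
        assert abs(peak - g.pore_radius) < max(0.05 * g.pore_radius, 25e-9)


class TestGradients:
    def test_uniform_field_zero_gradient(self):
        pf = PoreField(MagneticEnvironment(film_saturation=0.0),
                       DeviceGeometry(3e-6))
        gr, gz = pf.grad_b_squared_cyl(1.2e-6, 0.3e-6)
        assert abs(float(gr)) < 1e-6 and abs(float(gz)) < 1e-6

    def test_magnitude_grows_toward_rim(self, pf3):
        # along the membrane surface, |∇B²| increases from 500 nm to 100 nm
        c = pf3.geometry.pore_radius
        s = np.array([500e-9, 400e-9, 300e-9, 200e-9, 100e-9])
        gr, gz = pf3.grad_b_squared_cyl(c + s, np.full_like(s, 50e-9))
        mags = np.hypot(gr, gz)
        assert np.all(np.diff(mags) > 0)

    def test_step_convergence(self, pf3):
        # central differences converged: 0.5 nm vs 0.125 nm agree to 1e-4
        c = pf3.geometry.pore_radius
        g1 = pf3.grad_b_squared_cyl(c, 100e-9, step=0.5e-9)
        g2 = pf3.grad_b_squared_cyl(c, 100e-9, step=0.125e-9)
        for a, b in zip(g1, g2):
            assert float(a) == pytest.approx(float(b), rel=1e-4)

    def test_cached_table_matches_direct(self, env, pf3):
        table = FieldTable(env, pf3.geometry)
        pts = [(0.8e-6, 0.4e-6), (1.45e-6, 0.15e-6), (1.62e-6, 0.08e-6)]
        for rho, z in pts:
            br_t, bz_t = table.b_cyl(rho, z)
            br_d, bz_d = pf3.b_cyl(rho, z)
            assert float(br_t) == pytest.approx(float(br_d), abs=2e-4)
            assert float(bz_t) == pytest.approx(float(bz_d), abs=2e-4)
            gr_t, gz_t = table.grad_b_squared_cyl(rho, z)
            gr_d, gz_d = pf3.grad_b_squared_cyl(rho, z)
            scale = max(abs(float(gr_d)), abs(float(gz_d)))
            assert float(gr_t) == pytest.approx(float(gr_d), abs=0.02 * scale)
            assert float(gz_t) == pytest.approx(float(gz_d), abs=0.02 * scale)


class TestFilmModel:
    def test_demag_limited_below_material_saturation(self):
        m = demag_limited_magnetization(0.4)
        assert 0 < m < NIFE_SATURATION
        # µ0·M ≈ 0.18 T for the canonical permeability at 0.4 T drive
        assert m * MU0 == pytest.approx(0.183, abs=0.002)

    def test_saturated_alternative(self):
        env = MagneticEnvironment.saturated()
        assert env.film_saturation == pytest.approx(NIFE_SATURATION)

    def test_h_drive_alternative(self):
        env = MagneticEnvironment.from_applied_h(341_000.0)
        assert env.b_external == pytest.approx(0.4285, abs=2e-3)
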