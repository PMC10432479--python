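import math

import numpy as np
import pytest

from tenposim.device_model import DeviceGeometry
from tenposim.magnetostatics import MagneticEnvironment
from tenposim.particle_transport import (ParticleComplex, TrackingError,
                                         complex_susceptibility,
                                         magnetophoretic_force, stokes_drag)

ML_PER_H = 1e-6 / 3600.0


class TestSusceptibility:
    def test_canonical_levels(self):
        assert ParticleComplex.strong().relative_permeability == 1.00089
        assert ParticleComplex.weak().relative_permeability == 1.00009
        assert complex_susceptibility(15) == pytest.approx(8.9e-4)
        assert complex_susceptibility(1) == pytest.approx(9e-5)
        assert complex_susceptibility(0) == 0.0

    def test_interpolated_counts_bracketed(self):
        chi8 = complex_susceptibility(8)
        assert 9e-5 < chi8 < 8.9e-4

    def test_negative_count_rejected(self):
        with pytest.raises(TrackingError):
            complex_susceptibility(-1)

    def test_complex_volume_consistency(self):
        p = ParticleComplex.strong()
        assert p.volume == pytest.approx(math.pi / 6 * (200e-9) ** 3)
        assert p.volume > math.pi / 6 * p.ev_diameter**3


class TestStokesDrag:
    def test_zero_velocity(self):
        assert np.allclose(stokes_drag([0, 0, 0], 100e-9), 0.0)

    def test_hand_value(self):
        # 100 nm sphere in water at the 3 µm pore's mean speed
        f = stokes_drag([0, 0, 18.5e-6], 100e-9)
        assert abs(f[2]) == pytest.approx(3.49e-14, rel=0.01)

    def test_odd_in_velocity(self):
        v = np.array([1e-6, -2e-6, 3e-6])
        assert np.allclose(stokes_drag(v, 1e-7), -stokes_drag(-v, 1e-7))


class TestMagnetophoreticForce:
    def test_uniform_field_no_force(self):
        env = MagneticEnvironment(film_saturation=0.0)
        f = magnetophoretic_force([1e-6, 0, 0.5e-6], ParticleComplex.strong(),
                                  env, DeviceGeometry(3e-6))
        assert np.linalg.norm(f) < 1e-25

    def test_linear_in_susceptibility(self):
        env = MagneticEnvironment()
        g = DeviceGeometry(3e-6)
        pos = [1.4e-6, 0, 0.2e-6]
        f_w = magnetophoretic_force(pos, ParticleComplex.weak(), env, g)
        f_s = magnetophoretic_force(pos, ParticleComplex.strong(), env, g)
        ratio = ParticleComplex.strong().susceptibility / \
            ParticleComplex.weak().susceptibility
        assert np.allclose(f_s, ratio * f_w, rtol=1e-12)

    def test_energy_gradient_oracle(self):
        # |F| matches the finite-difference gradient of the interaction
        # energy U = −V χ |B|²/(2µ0) near the rim to 1e-3 relative
        from tenposim.magnetostatics import MU0, PoreField
        env = MagneticEnvironment()
        g = DeviceGeometry(3e-6)
        p = ParticleComplex.strong()
        pf = PoreField(env, g)
        pos = np.array([g.pore_radius - 100e-9, 0.0, 80e-9])
        f = magnetophoretic_force(pos, p, env, g)
        k = p.volume * p.susceptibility / (2 * MU0)
        h = 0.2e-9
        grad = []
        for axis in (0, 2):
            dp = pos.copy(); dm = pos.copy()
            dp[axis] += h; dm[axis] -= h
            bp = pf.pore_field(dp); bm = pf.pore_field(dm)
            grad.append(k * (bp @ bp - bm @ bm) / (2 * h))
        assert f[0] == pytest.approx(grad[0], rel=1e-3)
        assert f[2] == pytest.approx(grad[1], rel=1e-3)


@pytest.fixture()
def tracker_factory(engine, flow25, geo1):
    def make(particle):
        return engine.tracker(geo1, flow25, particle)
    return make


class TestTracking:
    def test_passive_axis_release_escapes(self, tracker_factory):
        tr = tracker_factory(ParticleComplex.untagged())
        out = tr.track_particle([0.05e-6, 3e-6])
        assert out.status == "escaped"

    def test_unphysically_strong_tag_captured(self, engine, flow25, geo1):
        # with χ = 10 the rim trap dominates any release over the pore
        # edge region (on the axis itself such a particle is repelled:
        # the pore center is a |B|² minimum)
        p = ParticleComplex(n_mnps=15, relative_permeability=11.0,
                            label="giant")
        tr = engine.tracker(geo1, flow25, p)
        out = tr.track_particle([0.6e-6, 1.0e-6])
        assert out.status == "captured"

    def test_mirror_symmetric_releases(self, tracker_factory):
        from tenposim.experiments import square_cell_radius
        tr = tracker_factory(ParticleComplex.weak())
        for xy in ([0.7e-6, 0.3e-6], [-0.9e-6, 0.9e-6]):
            r1 = square_cell_radius([xy])[0]
            r2 = square_cell_radius([[-xy[0], -xy[1]]])[0]
            assert r1 == r2
            o1 = tr.track_batch(np.array([r1])).outcomes[0]
            o2 = tr.track_batch(np.array([r2])).outcomes[0]
            assert o1.status == o2.status

    def test_captured_center_near_surface(self, tracker_factory):
        tr = tracker_factory(ParticleComplex.strong())
        out = tr.track_particle([0.9e-6, 3e-6])
        assert out.status == "captured"
        rho, z = out.final_position
        assert tr.solid_distance(rho, z) <= tr.particle.radius

    def test_path_recording(self, tracker_factory):
        tr = tracker_factory(ParticleComplex.strong())
        out = tr.track_particle([0.5e-6, 3e-6], record_path=True)
        assert out.path is not None and out.path.shape[0] > 10
        assert np.allclose(out.path[0], out.release_point)

    def test_refinement_invariance(self, engine, flow25, geo1):
        # outcomes stable under a halved integrator tolerance (≥ 98/100)
        from tenposim.experiments import ReleaseGrid
        grid = ReleaseGrid()
        radii = grid.cell_radii(geo1.pore_diameter)
        base = engine.tracker(geo1, flow25, ParticleComplex.weak())
        fine = engine.tracker(geo1, flow25, ParticleComplex.weak())
        fine.options = fine.options.scaled(0.5)
        s1 = base.track_batch(radii).statuses
        s2 = fine.track_batch(radii).statuses
        agree = sum(a == b for a, b in zip(s1, s2))
        assert agree >= 98
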