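import math
import warnings

import numpy as np
import pytest

from tenposim.device_model import DeviceGeometry
from tenposim.experiments import ReleaseGrid, square_cell_radius


class TestReleaseGrid:
    def test_grid_invariants(self):
        grid = ReleaseGrid()
        pts = grid.points(3e-6)
        assert pts.shape == (100, 2)
        # side exactly twice the pore diameter
        assert pts[:, 0].max() - pts[:, 0].min() == pytest.approx(6e-6)
        assert pts[:, 1].max() - pts[:, 1].min() == pytest.approx(6e-6)
        assert grid.height == pytest.approx(3e-6)

    def test_cell_mapping_preserves_enclosed_area(self):
        # the square streamtube max(|x|,|y|) = m and its image circle
        # enclose the same area (hence the same inflow flux)
        for m in (0.3e-6, 1e-6, 2.7e-6):
            rho = square_cell_radius([[m, 0.4 * m]])[0]
            assert math.pi * rho**2 == pytest.approx(4 * m**2)

    def test_all_points_inside_unit_cell(self):
        for d in (0.6e-6, 1e-6, 3e-6, 12e-6):
            g = DeviceGeometry(d)
            radii = ReleaseGrid().cell_radii(d)
            assert np.all(radii < g.unit_cell_radius)


class TestCaptureRate:
    def test_fraction_bounds_and_counts(self, canonical_rates):
        for s in canonical_rates.values():
            assert 0.0 <= s.capture_fraction <= 1.0
            assert s.n_released == 100
            assert s.n_captured + s.n_escaped + s.n_unresolved == 100

    def test_strong_dominates_weak(self, canonical_rates):
        for d in ("1um", "3um"):
            assert canonical_rates[(d, "strong")].capture_fraction >= \
                canonical_rates[(d, "weak")].capture_fraction

    def test_deterministic(self, engine, flow25, geo1, canonical_rates):
        repeat = engine.capture_rate(geo1, flow25, "strong")
        assert repeat.capture_fraction == \
            canonical_rates[("1um", "strong")].capture_fraction

    def test_untagged_wide_pore_escapes(self, engine, flow25):
        # no magnetics, 12 µm pore: essentially no geometric interception
        g = DeviceGeometry(12e-6)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = engine.capture_rate(g, flow25, "untagged")
        assert s.capture_fraction <= 0.02


class TestMultiMembrane:
    def test_single_pass_equals_capture_rate(self, engine, flow25, geo3,
                                             canonical_rates):
        s = engine.multi_membrane_capture(geo3, flow25, "strong", 1, seed=7)
        assert s.capture_fraction == \
            canonical_rates[("3um", "strong")].capture_fraction

    def test_cumulative_non_decreasing(self, engine, flow25, geo3):
        s = engine.multi_membrane_capture(geo3, flow25, "strong", 5, seed=3)
        assert all(b >= a for a, b in zip(s.cumulative, s.cumulative[1:]))

    def test_seeded_reproducibility(self, engine, flow25, geo3):
        a = engine.multi_membrane_capture(geo3, flow25, "strong", 3, seed=11)
        b = engine.multi_membrane_capture(geo3, flow25, "strong", 3, seed=11)
        assert a.cumulative == b.cumulative

    def test_independent_pass_closed_form(self, engine, flow25, geo3):
        # with uniform random re-release, passes are independent with a
        # homogenized per-pass capture probability ≈ R1, so the cumulative
        # capture approaches 1 − (1 − R1)^n within binomial error
        r1 = engine.capture_rate(geo3, flow25, "strong").capture_fraction
        n = 3
        vals = [engine.multi_membrane_capture(geo3, flow25, "strong", n,
                                              seed=s).capture_fraction
                for s in range(20)]
        expected = 1 - (1 - r1) ** n
        sem = math.sqrt(expected * (1 - expected) / 100) / math.sqrt(20)
        assert np.mean(vals) == pytest.approx(expected, abs=max(5 * sem, 0.03))

    def test_invalid_membrane_count(self, engine, flow25, geo3):
        with pytest.raises(ValueError):
            engine.multi_membrane_capture(geo3, flow25, "strong", 0)


class TestScanAndDiagnostics:
    def test_empty_scan_empty_table(self, engine):
        table = engine.scan_parameters(diameters=[], flow_rates_mlh=[])
        assert table.shape[0] == 0
        assert "capture_fraction" in table.columns

    def test_scan_row_schema(self, engine):
        table = engine.scan_parameters(diameters=[1e-6],
                                       flow_rates_mlh=[2.5],
                                       scenarios=("strong",))
        assert table.shape[0] == 1
        row = table.iloc[0]
        assert row["d_um"] == pytest.approx(1.0)
        assert row["phi_ml_per_h"] == pytest.approx(2.5)
        assert row["status"] == "ok"

    def test_scan_survives_bad_condition(self, engine):
        table = engine.scan_parameters(diameters=[-1e-6, 1e-6],
                                       flow_rates_mlh=[2.5],
                                       scenarios=("strong",))
        assert table.shape[0] == 2
        assert table.iloc[0]["status"].startswith("error")
        assert table.iloc[1]["status"] == "ok"

    def test_occlusion_redistribution(self, engine):
        assert engine.occlusion_array_experiment(0) == 0.0
        assert engine.occlusion_array_experiment(4) == pytest.approx(80.0)
        assert engine.occlusion_array_experiment(1) == pytest.approx(12.5)
        vals = [engine.occlusion_array_experiment(k) for k in range(5)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        with pytest.raises(ValueError):
            engine.occlusion_array_experiment(9)

    def test_force_ratio_sentinel_without_film(self, flow25, geo3):
        from tenposim.experiments import ExperimentEngine
        from tenposim.magnetostatics import MagneticEnvironment
        eng = ExperimentEngine(env=MagneticEnvironment(film_saturation=0.0))
        assert eng.force_ratio_diagnostic(geo3, flow25, "strong") == -math.inf

    def test_force_ratio_strong_exceeds_weak_by_one_order(self, engine,
                                                          flow25, geo3):
        s = engine.force_ratio_diagnostic(geo3, flow25, "strong")
        w = engine.force_ratio_diagnostic(geo3, flow25, "weak")
        assert s - w == pytest.approx(1.0, abs=0.01)
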