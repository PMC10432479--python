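import warnings

import pytest
from hypothesis import HealthCheck, settings

from tenposim import DeviceGeometry, ExperimentEngine, FlowCondition

settings.register_profile(
    "ci", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

ML_PER_H = 1e-6 / 3600.0


@pytest.fixture(scope="session")
def engine():
    """Shared experiment engine: Stokes solutions and field tables are
    cached across the whole test session."""
    return ExperimentEngine()


@pytest.fixture(scope="session")
def flow25():
    return FlowCondition(volumetric_flow_rate=2.5 * ML_PER_H)


@pytest.fixture(scope="session")
def geo1():
    return DeviceGeometry(pore_diameter=1e-6)


@pytest.fixture(scope="session")
def geo3():
    return DeviceGeometry(pore_diameter=3e-6)


@pytest.fixture(scope="session")
def canonical_rates(engine, flow25, geo1, geo3):
    """Single-membrane capture fractions of the canonical 1 µm / 3 µm runs."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            ("1um", "strong"): engine.capture_rate(geo1, flow25, "strong"),
            ("1um", "weak"): engine.capture_rate(geo1, flow25, "weak"),
            ("3um", "strong"): engine.capture_rate(geo3, flow25, "strong"),
            ("3um", "weak"): engine.capture_rate(geo3, flow25, "weak"),
        }
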