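"""Run configuration: YAML files with explicit units, canonical fixtures.

Configuration files carry every physical quantity as a ``"<number> <unit>"``
string (µm, nm, mL/h, cm², T, Pa·s, A/m); values are converted to SI at
load time and all internal computation is SI.  Unknown keys and
non-physical values raise descriptive validation errors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .device_model import DeviceGeometry, FlowCondition
from .magnetostatics import MagneticEnvironment, NIFE_SATURATION
from .units import parse_quantity


class ConfigError(ValueError):
    """Malformed or non-physical run configuration."""


_GEOMETRY_KEYS = {"pore_diameter", "pore_density", "membrane_area",
                  "nife_thickness", "backing_thickness", "n_membranes"}
_FLOW_KEYS = {"volumetric_flow_rate", "dynamic_viscosity"}
_ENV_KEYS = {"b_external", "film_saturation", "film_model"}
_TOP_KEYS = {"geometry", "flow", "environment", "scenarios", "scan",
             "clog_radii", "seed", "output_dir", "label"}
_SCAN_KEYS = {"diameters", "flow_rates", "n_membranes"}


@dataclass
class RunConfig:
    """Validated run configuration (all quantities SI)."""

    geometry: DeviceGeometry = field(default_factory=lambda: DeviceGeometry(3e-6))
    flow: FlowCondition = field(
        default_factory=lambda: FlowCondition(2.5e-6 / 3600))
    environment: MagneticEnvironment = field(default_factory=MagneticEnvironment)
    scenarios: tuple = ("strong", "weak")
    scan_diameters: tuple = ()        # m
    scan_flow_rates: tuple = ()       # m³/s
    scan_n_membranes: tuple = (1,)
    clog_radii: tuple = ()            # m
    seed: int = 0
    output_dir: str = "results"
    label: str = "run"

    def to_dict(self) -> dict:
        """Unit-annotated plain dict (round-trips through load)."""
        return {
            "label": self.label,
            "seed": self.seed,
            "output_dir": self.output_dir,
            "geometry": {
                "pore_diameter": f"{self.geometry.pore_diameter * 1e6:.9g} um",
                "pore_density": f"{self.geometry.pore_density / 1e4:.9g} 1/cm^2",
                "membrane_area": f"{self.geometry.membrane_area * 1e4:.9g} cm^2",
                "nife_thickness": f"{self.geometry.nife_thickness * 1e9:.9g} nm",
                "backing_thickness":
                    f"{self.geometry.backing_thickness * 1e6:.9g} um",
                "n_membranes": self.geometry.n_membranes,
            },
            "flow": {
                "volumetric_flow_rate":
                    f"{self.flow.volumetric_flow_rate / (1e-6 / 3600):.9g} mL/h",
                "dynamic_viscosity":
                    f"{self.flow.dynamic_viscosity * 1e3:.9g} mPa.s",
            },
            "environment": {
                "b_external": f"{self.environment.b_external:.9g} T",
                "film_saturation":
                    f"{self.environment.film_saturation:.9g} A/m",
            },
            "scenarios": list(self.scenarios),
            "scan": {
                "diameters": [f"{d * 1e6:.9g} um" for d in self.scan_diameters],
                "flow_rates": [f"{q / (1e-6 / 3600):.9g} mL/h"
                               for q in self.scan_flow_rates],
                "n_membranes": list(self.scan_n_membranes),
            },
            "clog_radii": [f"{r * 1e9:.9g} nm" for r in self.clog_radii],
        }

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _check_keys(section: dict, allowed: set, where: str):
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"unknown key(s) {sorted(unknown)} in {where}")


def config_from_dict(data: dict | None) -> RunConfig:
    """Build and validate a RunConfig from a plain (YAML) dict."""
    data = data or {}
    if not isinstance(data, dict):
        raise ConfigError("top-level config must be a mapping")
    _check_keys(data, _TOP_KEYS, "config")
    try:
        gsec = dict(data.get("geometry") or {})
        _check_keys(gsec, _GEOMETRY_KEYS, "geometry")
        gkw = {}
        for key, dim in [("pore_diameter", "length"),
                         ("pore_density", "areal density"),
                         ("membrane_area", "area"),
                         ("nife_thickness", "length"),
                         ("backing_thickness", "length")]:
            if key in gsec:
                gkw[key] = parse_quantity(gsec[key], dim)
        if "n_membranes" in gsec:
            gkw["n_membranes"] = int(gsec["n_membranes"])
        geometry = DeviceGeometry(**{"pore_diameter": 3e-6, **gkw})

        fsec = dict(data.get("flow") or {})
        _check_keys(fsec, _FLOW_KEYS, "flow")
        fkw = {}
        if "volumetric_flow_rate" in fsec:
            fkw["volumetric_flow_rate"] = parse_quantity(
                fsec["volumetric_flow_rate"], "flow rate")
        if "dynamic_viscosity" in fsec:
            fkw["dynamic_viscosity"] = parse_quantity(
                fsec["dynamic_viscosity"], "viscosity")
        flow = FlowCondition(**{"volumetric_flow_rate": 2.5e-6 / 3600, **fkw})

        esec = dict(data.get("environment") or {})
        _check_keys(esec, _ENV_KEYS, "environment")
        ekw = {}
        if "b_external" in esec:
            ekw["b_external"] = parse_quantity(esec["b_external"], "flux density")
        if esec.get("film_model") == "saturated":
            ekw["film_saturation"] = NIFE_SATURATION
        if "film_saturation" in esec:
            ekw["film_saturation"] = parse_quantity(
                esec["film_saturation"], "magnetization")
        environment = MagneticEnvironment(**ekw)

        ssec = dict(data.get("scan") or {})
        _check_keys(ssec, _SCAN_KEYS, "scan")
        scan_d = tuple(parse_quantity(v, "length")
                       for v in (ssec.get("diameters") or []))
        scan_q = tuple(parse_quantity(v, "flow rate")
                       for v in (ssec.get("flow_rates") or []))
        scan_n = tuple(int(v) for v in (ssec.get("n_membranes") or [1]))
        clogs = tuple(parse_quantity(v, "length")
                      for v in (data.get("clog_radii") or []))
        scenarios = tuple(data.get("scenarios") or ("strong", "weak"))
        for s in scenarios:
            if s not in ("strong", "weak", "untagged"):
                raise ConfigError(f"unknown scenario {s!r}")
    except ConfigError:
        raise
    except (ValueError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc

    return RunConfig(
        geometry=geometry, flow=flow, environment=environment,
        scenarios=scenarios, scan_diameters=scan_d, scan_flow_rates=scan_q,
        scan_n_membranes=scan_n, clog_radii=clogs,
        seed=int(data.get("seed", 0)),
        output_dir=str(data.get("output_dir", "results")),
        label=str(data.get("label", "run")),
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration; empty file → defaults."""
    text = Path(path).read_text()
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    return config_from_dict(data)


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def fixture_scenarios() -> dict[str, RunConfig]:
    """The canonical ready-to-run scenario set.

    * ``fig2b`` — pore-diameter scan at ɸ = 2.5 mL/h, a = 2.5 cm²;
    * ``fig2c`` — flow-rate scan at d = 1 µm;
    * ``membranes`` — membrane-number iteration n = 1..5 at d = 3 µm;
    * ``clog`` — 400/800 nm rim clogs on a d = 3 µm pore;
    * ``occlusion`` — nine-pore parallel cell with 0..4 pores blocked;
    * ``forces`` — force-ratio diagnostics at the pore edge.
    """
    base = dict(seed=0)
    fixtures = {
        "fig2b": config_from_dict({
            **base, "label": "fig2b",
            "scan": {"diameters": ["0.6 um", "1 um", "3 um", "12 um"],
                     "flow_rates": ["2.5 mL/h"]},
        }),
        "fig2c": config_from_dict({
            **base, "label": "fig2c",
            "geometry": {"pore_diameter": "1 um"},
            "scan": {"diameters": ["1 um"],
                     "flow_rates": ["0.5 mL/h", "1 mL/h", "2.5 mL/h",
                                    "5 mL/h", "10 mL/h", "25 mL/h"]},
        }),
        "membranes": config_from_dict({
            **base, "label": "membranes",
            "geometry": {"pore_diameter": "3 um"},
            "scan": {"diameters": ["3 um"], "flow_rates": ["2.5 mL/h"],
                     "n_membranes": [1, 2, 3, 4, 5]},
        }),
        "clog": config_from_dict({
            **base, "label": "clog",
            "geometry": {"pore_diameter": "3 um"},
            "clog_radii": ["400 nm", "800 nm"],
        }),
        "occlusion": config_from_dict({
            **base, "label": "occlusion",
            "geometry": {"pore_diameter": "3 um"},
        }),
        "forces": config_from_dict({
            **base, "label": "forces",
            "scan": {"diameters": ["0.6 um", "1 um", "3 um", "12 um"],
                     "flow_rates": ["2.5 mL/h"]},
        }),
    }
    return fixtures
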