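"""In-silico device experiments: capture-rate grids, scans, diagnostics.

Reproduces the canonical numerical experiments on a single magnetic
nanopore and its unit cell:

* ``capture_rate`` — fraction of 100 EV–MNP complexes, released from a
  uniform 10×10 grid of side 2d at 3 µm above the pore, that are
  magnetically captured (Rs for strongly-tagged, Rw for weakly-tagged);
* ``multi_membrane_capture`` — the membrane-stacking iteration in which
  uncaptured particles re-enter the next membrane at a random lateral
  position;
* ``scan_parameters`` — sweeps over pore diameter, flow rate and membrane
  count;
* ``force_ratio_diagnostic`` — magnetophoretic force vs drag at a probe
  point near the pore edge;
* ``occlusion_array_experiment`` / ``clog_impact_experiment`` — array-
  scale flow redistribution under fully blocked pores, and the effect of
  a rim-lodged spherical clog on a single pore's capture rates.

The paper's square periodic unit cell is axisymmetrized: a release point
(x, y) maps to the cylindrical-cell radius ρ = (2/√π)·max(|x|, |y|),
which preserves both the enclosed flux of the square streamtube through
that point and the local outside-flux fraction at its azimuth.

Trajectories are integrated against the cached numerical Stokes field of
the unit cell (one factorization per geometry, rescaled linearly in flow
rate) and the cached magnetic force table.  Capture counts only within a
residence budget of 10 advective transit times; slower membrane-creep
trajectories end as ``max-steps`` and count as not captured.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .device_model import (DeviceGeometry, FlowCondition, mean_pore_velocity,
                           occlusion_flow_multiplier)
from .hydrodynamics import ClogSpec, SemiAnalyticPoreFlow
from .magnetostatics import MU0, FieldTable, MagneticEnvironment, PoreField
from .particle_transport import (IntegratorOptions, ParticleComplex,
                                 PoreTracker, STATUS_CAPTURED,
                                 STATUS_MAX_STEPS)
from .stokes_ref import StokesVelocityField, solve_axisymmetric_stokes

#: Canonical scan values (pore diameters in m, flow rates in mL/h).
CANONICAL_DIAMETERS = (0.6e-6, 1e-6, 3e-6, 12e-6)
CANONICAL_FLOW_RATES_MLH = (0.5, 2.5, 10.0, 25.0)
FLOW_SCAN_MLH = (0.5, 1.0, 2.5, 5.0, 10.0, 25.0)

#: Residence budget, in units of the advective transit time.
RESIDENCE_BUDGET_FACTOR = 10.0

ML_PER_H = 1e-6 / 3600.0

SCENARIOS = {
    "strong": ParticleComplex.strong,
    "weak": ParticleComplex.weak,
    "untagged": ParticleComplex.untagged,
}


@dataclass(frozen=True)
class ReleaseGrid:
    """Uniform square release grid: 10×10 points, side 2d, 3 µm up.

    The grid is centered on the pore axis; its side is exactly twice the
    pore diameter and all points sit at the same height.
    """

    n_side: int = 10
    height: float = 3.0e-6
    side_factor: float = 2.0  # side length in units of the pore diameter

    @property
    def count(self) -> int:
        return self.n_side**2

    def points(self, pore_diameter: float) -> np.ndarray:
        """(n², 2) lateral (x, y) release coordinates."""
        half = 0.5 * self.side_factor * pore_diameter
        xs = np.linspace(-half, half, self.n_side)
        X, Y = np.meshgrid(xs, xs)
        return np.stack([X.ravel(), Y.ravel()], axis=1)

    def cell_radii(self, pore_diameter: float) -> np.ndarray:
        """Axisymmetrized release radii of the grid points."""
        return square_cell_radius(self.points(pore_diameter))


def square_cell_radius(xy: np.ndarray) -> np.ndarray:
    """Map square-cell lateral positions to cylindrical-cell radii.

    ρ_eff = (2/√π)·max(|x|, |y|): the square streamtube through (x, y)
    [level set of the cell coordinate max(|x|,|y|)] is mapped to the
    circle enclosing the same flux; the local outside-flux fraction per
    azimuth is preserved exactly as well.
    """
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    return (2.0 / math.sqrt(math.pi)) * np.max(np.abs(xy), axis=1)


@dataclass
class CaptureSummary:
    """Result of one capture-rate condition (per scenario)."""

    pore_diameter: float
    flow_rate: float            # m³/s
    n_membranes: int
    membrane_area: float
    scenario: str
    capture_fraction: float
    n_released: int
    n_captured: int
    n_escaped: int
    n_unresolved: int           # step/residence budget exhausted
    seed: int | None = None
    cumulative: list[float] = field(default_factory=list)

    def as_row(self) -> dict:
        return {
            "d_um": self.pore_diameter * 1e6,
            "phi_ml_per_h": self.flow_rate / ML_PER_H,
            "n_membranes": self.n_membranes,
            "area_cm2": self.membrane_area * 1e4,
            "scenario": self.scenario,
            "capture_fraction": self.capture_fraction,
            "n_released": self.n_released,
            "n_captured": self.n_captured,
            "n_escaped": self.n_escaped,
            "n_unresolved": self.n_unresolved,
            "seed": -1 if self.seed is None else self.seed,
        }


class ExperimentEngine:
    """Runs capture experiments with cached field/flow solutions.

    One engine caches, per pore geometry (and clog), the factorized
    Stokes unit-cell solution and the magnetic force table, so scans
    re-use them across flow rates and scenarios.
    """

    def __init__(self, env: MagneticEnvironment | None = None,
                 nr: int = 144, nz: int = 288,
                 options: IntegratorOptions | None = None,
                 grid: ReleaseGrid | None = None):
        self.env = env or MagneticEnvironment()
        self.nr, self.nz = nr, nz
        self.base_options = options or IntegratorOptions()
        self.grid = grid or ReleaseGrid()
        self._stokes_cache: dict = {}
        self._table_cache: dict = {}

    # -- cached solvers -----------------------------------------------------
    def _geo_key(self, g: DeviceGeometry):
        return (round(g.pore_diameter, 15), round(g.pore_density, 3),
                round(g.pore_length, 15), round(g.membrane_area, 12))

    def stokes_field(self, geometry: DeviceGeometry, flow: FlowCondition,
                     clog: ClogSpec | None = None) -> StokesVelocityField:
        key = (self._geo_key(geometry),
               None if clog is None else round(clog.clog_radius, 12),
               round(flow.dynamic_viscosity, 9))
        if key not in self._stokes_cache:
            ref_flow = FlowCondition(2.5 * ML_PER_H, flow.dynamic_viscosity)
            sol = solve_axisymmetric_stokes(geometry, ref_flow, clog=clog,
                                            nr=self.nr, nz=self.nz)
            self._stokes_cache[key] = StokesVelocityField(
                sol, z_top=max(3.5e-6, 2 * geometry.pore_diameter))
        return self._stokes_cache[key].rescaled(flow)

    def field_table(self, geometry: DeviceGeometry) -> FieldTable:
        key = (self._geo_key(geometry), round(self.env.b_external, 9),
               round(self.env.film_saturation, 3))
        if key not in self._table_cache:
            self._table_cache[key] = FieldTable(self.env, geometry)
        return self._table_cache[key]

    def residence_budget(self, geometry: DeviceGeometry,
                         flow: FlowCondition) -> float:
        """Residence budget: 10 advective transits of approach + channel."""
        vz = mean_pore_velocity(geometry, flow)
        if vz == 0:
            return math.inf
        transit = (self.grid.height + geometry.pore_length) / vz
        return RESIDENCE_BUDGET_FACTOR * transit

    def tracker(self, geometry: DeviceGeometry, flow: FlowCondition,
                particle: ParticleComplex,
                clog: ClogSpec | None = None) -> PoreTracker:
        opts = IntegratorOptions(**{**self.base_options.__dict__})
        opts.max_time = self.residence_budget(geometry, flow)
        return PoreTracker(geometry, flow, self.env, particle,
                           velocity_field=self.stokes_field(geometry, flow, clog),
                           field_table=self.field_table(geometry),
                           clog=clog, options=opts)

    # -- operations ---------------------------------------------------------
    def _resolve_particle(self, scenario) -> ParticleComplex:
        if isinstance(scenario, ParticleComplex):
            return scenario
        return SCENARIOS[scenario]()

    def capture_rate(self, geometry: DeviceGeometry, flow: FlowCondition,
                     scenario, clog: ClogSpec | None = None) -> CaptureSummary:
        """Capture fraction of the 100-point release grid (deterministic)."""
        particle = self._resolve_particle(scenario)
        tr = self.tracker(geometry, flow, particle, clog)
        radii = self.grid.cell_radii(geometry.pore_diameter)
        res = tr.track_batch(radii, release_z=self.grid.height)
        statuses = res.statuses
        n_cap = statuses.count(STATUS_CAPTURED)
        n_unres = statuses.count(STATUS_MAX_STEPS)
        if n_unres:
            warnings.warn(
                f"{n_unres} trajectories exceeded the step/residence budget "
                f"(d={geometry.pore_diameter*1e6:g} µm, "
                f"{particle.label or 'custom'}); counted as not captured",
                stacklevel=2)
        n = len(statuses)
        return CaptureSummary(
            pore_diameter=geometry.pore_diameter,
            flow_rate=flow.volumetric_flow_rate,
            n_membranes=1,
            membrane_area=geometry.membrane_area,
            scenario=particle.label or "custom",
            capture_fraction=n_cap / n,
            n_released=n,
            n_captured=n_cap,
            n_escaped=n - n_cap - n_unres,
            n_unresolved=n_unres,
        )

    def multi_membrane_capture(self, geometry: DeviceGeometry,
                               flow: FlowCondition, scenario, n: int,
                               seed: int = 0) -> CaptureSummary:
        """Cumulative capture over n membranes in series.

        Pass 1 releases the canonical grid; particles not captured by
        membrane k re-enter membrane k+1 at a uniformly random lateral
        position over the same 2d × 2d square (pore positions of stacked
        membranes are independent), with a seeded generator.
        """
        if n < 1:
            raise ValueError("need at least one membrane")
        particle = self._resolve_particle(scenario)
        tr = self.tracker(geometry, flow, particle)
        rng = np.random.default_rng(seed)
        d = geometry.pore_diameter
        half = 0.5 * self.grid.side_factor * d
        radii = self.grid.cell_radii(d)
        total = radii.size
        captured_total = 0
        unresolved_total = 0
        cumulative = []
        for _ in range(n):
            if radii.size:
                res = tr.track_batch(radii, release_z=self.grid.height)
                st = res.statuses
                captured_total += st.count(STATUS_CAPTURED)
                unresolved_total += st.count(STATUS_MAX_STEPS)
            cumulative.append(captured_total / total)
            m = total - captured_total
            xy = rng.uniform(-half, half, size=(m, 2))
            radii = square_cell_radius(xy)
        return CaptureSummary(
            pore_diameter=d,
            flow_rate=flow.volumetric_flow_rate,
            n_membranes=n,
            membrane_area=geometry.membrane_area,
            scenario=particle.label or "custom",
            capture_fraction=cumulative[-1],
            n_released=total,
            n_captured=captured_total,
            n_escaped=total - captured_total,
            n_unresolved=unresolved_total,
            seed=seed,
            cumulative=cumulative,
        )

    def force_ratio_diagnostic(self, geometry: DeviceGeometry,
                               flow: FlowCondition, scenario,
                               probe_distance: float = 100e-9) -> float:
        """log10 of |vertical magnetophoretic force| / |Stokes drag|.

        Probe point: straight above the rim corner, (ρ = d/2,
        z = +probe_distance) — the position of a complex resting on the
        pore's edge.  The drag is on a stationary complex in the local
        unperturbed fluid velocity.  Returns −inf if the film is
        unmagnetized.
        """
        particle = self._resolve_particle(scenario)
        c = geometry.pore_radius
        z = probe_distance
        pf = PoreField(self.env, geometry)
        if pf._in_film(np.asarray(c), np.asarray(z)):
            raise ValueError("probe point lies inside the film solid")
        _, gz = pf.grad_b_squared_cyl(np.asarray([c]), np.asarray([z]))
        f_z = abs(particle.volume * particle.susceptibility / (2 * MU0) * gz[0])
        if f_z == 0.0:
            return -math.inf
        sa = SemiAnalyticPoreFlow(geometry, flow)
        ur, uz = sa.velocity_cyl(c, z)
        speed = math.hypot(float(ur), float(uz))
        drag = 6 * math.pi * flow.dynamic_viscosity * particle.radius * speed
        return math.log10(f_z / drag)

    def scan_parameters(self, diameters=None, flow_rates_mlh=None,
                        scenarios=("strong", "weak"), n_membranes=(1,),
                        membrane_area: float = 2.5e-4,
                        viscosity: float = 1.0e-3,
                        seed: int = 0) -> pd.DataFrame:
        """Sweep conditions × scenarios; one row per CaptureSummary.

        Empty inputs produce an empty table.  A condition that raises is
        recorded with status "error" and the scan continues.
        """
        diameters = [] if diameters is None else list(diameters)
        flow_rates_mlh = [] if flow_rates_mlh is None else list(flow_rates_mlh)
        rows = []
        for d in diameters:
            for phi in flow_rates_mlh:
                for n in n_membranes:
                    for scen in scenarios:
                        row = {"status": "ok"}
                        try:
                            g = DeviceGeometry(pore_diameter=d,
                                               membrane_area=membrane_area)
                            fl = FlowCondition(phi * ML_PER_H, viscosity)
                            if n == 1:
                                s = self.capture_rate(g, fl, scen)
                            else:
                                s = self.multi_membrane_capture(
                                    g, fl, scen, n, seed=seed)
                            row.update(s.as_row())
                        except Exception as exc:  # record, keep scanning
                            row.update({"status": f"error: {exc}",
                                        "d_um": d * 1e6, "phi_ml_per_h": phi,
                                        "n_membranes": n, "scenario": str(scen)})
                        rows.append(row)
        columns = ["d_um", "phi_ml_per_h", "n_membranes", "area_cm2",
                   "scenario", "capture_fraction", "n_released", "n_captured",
                   "n_escaped", "n_unresolved", "seed", "status"]
        return pd.DataFrame(rows, columns=columns)

    def occlusion_array_experiment(self, n_occluded: int,
                                   n_pores_in_cell: int = 9) -> float:
        """Percent increase in maximal drag at an open pore when
        ``n_occluded`` of a periodic cell of parallel pores are blocked.

        At fixed total flow the blocked pores' flux redistributes evenly
        over the open ones; Stokes drag is linear in the flow, so the
        maximal drag on an entering complex grows by the same factor.
        """
        if n_occluded > n_pores_in_cell - 1:
            raise ValueError("cannot occlude every pore in the cell")
        mult = occlusion_flow_multiplier(n_pores_in_cell, n_occluded)
        return (mult - 1.0) * 100.0

    def clog_impact_experiment(self, clog: ClogSpec, geometry: DeviceGeometry,
                               flow: FlowCondition) -> dict:
        """ΔRs, ΔRw of a clogged pore relative to the clean baseline."""
        out = {}
        for scen in ("strong", "weak"):
            base = self.capture_rate(geometry, flow, scen)
            with_clog = self.capture_rate(geometry, flow, scen, clog=clog)
            out[f"R{scen[0]}_clean"] = base.capture_fraction
            out[f"R{scen[0]}_clogged"] = with_clog.capture_fraction
            out[f"delta_R{scen[0]}"] = (with_clog.capture_fraction
                                        - base.capture_fraction)
        return out


_default_engine: ExperimentEngine | None = None


def default_engine() -> ExperimentEngine:
    """Module-level engine with shared caches (canonical environment)."""
    global _default_engine
    if _default_engine is None:
        _default_engine = ExperimentEngine()
    return _default_engine
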