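"""Device geometry and per-pore hydraulics.

A TENPO device is a track-etched polycarbonate membrane (5 µm backing)
coated with a 200 nm NiFe film, pierced by a dense array of cylindrical
pores.  At the areal densities used here the pores act as independent
parallel hydraulic resistors: each pore owns a cylindrical unit cell of
radius ``(π · pore_density)^(-1/2)`` and carries an equal share of the
total volumetric flow.

All quantities are SI internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

WATER_VISCOSITY = 1.0e-3  # Pa·s, room temperature; configurable everywhere

#: Pore areal density implied by the d = 3 µm reference device
#: (5.3e6 pores over 2.5 cm²), in m⁻².
REFERENCE_DENSITY_3UM = 5.3e6 / 2.5e-4  # = 2.12e10 m^-2


class InvalidGeometryError(ValueError):
    """Raised when a device geometry is non-physical."""


def canonical_pore_density(pore_diameter: float) -> float:
    """Pore density (m⁻²) for the canonical scans at a given diameter.

    The canonical devices keep the open-area fraction — hence the mean
    in-pore velocity at fixed total flow — constant across pore diameters,
    anchored to the d = 3 µm reference membrane (2.12e6 cm⁻²).
    """
    if pore_diameter <= 0:
        raise InvalidGeometryError("pore diameter must be positive")
    return REFERENCE_DENSITY_3UM * (3e-6 / pore_diameter) ** 2


@dataclass(frozen=True)
class DeviceGeometry:
    """Membrane and pore-array geometry.

    Parameters
    ----------
    pore_diameter
        Pore diameter d (m).
    pore_density
        Pores per m² of membrane.  ``None`` selects the canonical
        constant-velocity density for this diameter.
    membrane_area
        Device cross-sectional area a (m²), default 2.5 cm².
    nife_thickness
        Magnetic film thickness (m), default 200 nm.
    backing_thickness
        Polycarbonate backing thickness (m), default 5 µm.
    n_membranes
        Number of membranes stacked in series.
    """

    pore_diameter: float
    pore_density: float | None = None
    membrane_area: float = 2.5e-4
    nife_thickness: float = 200e-9
    backing_thickness: float = 5e-6
    n_membranes: int = 1

    def __post_init__(self):
        if self.pore_diameter <= 0:
            raise InvalidGeometryError("pore diameter must be positive")
        if self.pore_density is None:
            object.__setattr__(
                self, "pore_density", canonical_pore_density(self.pore_diameter)
            )
        if self.pore_density <= 0:
            raise InvalidGeometryError("pore density must be positive")
        if self.membrane_area <= 0:
            raise InvalidGeometryError("membrane area must be positive")
        if self.nife_thickness <= 0 or self.backing_thickness <= 0:
            raise InvalidGeometryError("layer thicknesses must be positive")
        if self.n_membranes < 1:
            raise InvalidGeometryError("need at least one membrane")
        if self.unit_cell_radius <= self.pore_radius:
            raise InvalidGeometryError(
                "pores overlap: unit cell radius "
                f"{self.unit_cell_radius:.3g} m <= pore radius {self.pore_radius:.3g} m"
            )

    @property
    def pore_radius(self) -> float:
        return 0.5 * self.pore_diameter

    @property
    def pore_area(self) -> float:
        """Cross-sectional area of one pore (m²)."""
        return math.pi * self.pore_radius**2

    @property
    def unit_cell_radius(self) -> float:
        """Radius of the cylindrical unit cell owned by one pore (m)."""
        return (math.pi * self.pore_density) ** -0.5

    @property
    def pore_length(self) -> float:
        """Channel length seen by the flow: NiFe film plus backing (m)."""
        return self.nife_thickness + self.backing_thickness

    @property
    def open_area_fraction(self) -> float:
        return self.pore_density * self.pore_area

    def with_diameter(self, d: float, keep_density: bool = False) -> "DeviceGeometry":
        """Copy at a new diameter; density re-derived canonically by default."""
        return replace(
            self, pore_diameter=d,
            pore_density=self.pore_density if keep_density else None,
        )


def pore_count(geometry: DeviceGeometry) -> int:
    """Number of pores on one membrane, rounded to the nearest integer."""
    n = geometry.pore_density * geometry.membrane_area
    n_int = round(n)
    if n_int < 1:
        raise InvalidGeometryError("device has no pores")
    return int(n_int)


@dataclass(frozen=True)
class FlowCondition:
    """Operating flow through the whole device.

    ``volumetric_flow_rate`` is the total flow ɸ (m³/s) pushed through the
    membrane stack; each membrane sees the full ɸ, each pore ɸ/N.
    """

    volumetric_flow_rate: float
    dynamic_viscosity: float = WATER_VISCOSITY

    def __post_init__(self):
        if self.volumetric_flow_rate < 0:
            raise InvalidGeometryError("flow rate must be non-negative")
        if self.dynamic_viscosity <= 0:
            raise InvalidGeometryError("viscosity must be positive")

    def per_pore_flux(self, geometry: DeviceGeometry) -> float:
        """Volumetric flux through a single pore, ɸ/N (m³/s)."""
        return self.volumetric_flow_rate / pore_count(geometry)


def mean_pore_velocity(geometry: DeviceGeometry, flow: FlowCondition) -> float:
    """Average axial velocity in a pore, Vz = ɸ / (N · a_pore)  (m/s)."""
    n = pore_count(geometry)
    if n < 1:
        raise InvalidGeometryError("zero pore count")
    return flow.volumetric_flow_rate / (n * geometry.pore_area)


def pore_hydraulic_resistance(
    geometry: DeviceGeometry, viscosity: float = WATER_VISCOSITY
) -> float:
    """Hydraulic resistance ΔP/Q of a single pore (Pa·s/m³).

    Orifice end correction (Sampson, 3µ/r³) plus the Poiseuille channel
    term 8µL/(πr⁴) for a channel of length L = film + backing.  The L → 0
    limit is the bare orifice resistance.  Strictly decreasing in r.
    """
    r = geometry.pore_radius
    L = geometry.pore_length
    return 3.0 * viscosity / r**3 + 8.0 * viscosity * L / (math.pi * r**4)


def inter_pore_flow_resistance(
    geometry: DeviceGeometry,
    gap_height: float = 10e-6,
    viscosity: float = WATER_VISCOSITY,
) -> float:
    """Diagnostic: lateral flow resistance between adjacent pores (Pa·s/m³).

    Treats the fluid layer of height ``gap_height`` above the membrane as a
    plane-Poiseuille slit of width one unit-cell circumference and length
    one pore pitch: R ≈ 12 µ ℓ / (h³ w).  The spacer gap height of a real
    stack is not part of the device model, so this is order-of-magnitude
    only — it quantifies why flow redistributes freely between pores
    (lateral resistance ≪ through-pore resistance), and is not used by any
    solver.
    """
    pitch = geometry.pore_density**-0.5
    width = 2 * math.pi * geometry.unit_cell_radius
    return 12.0 * viscosity * pitch / (gap_height**3 * width)


def occlusion_flow_multiplier(n_pores_in_cell: int, n_occluded: int) -> float:
    """Per-open-pore flux multiplier when pores clog at fixed total flow.

    With identical parallel pores and total flux held fixed, blocking k of
    n pores redistributes their share evenly: multiplier = n / (n − k).
    """
    if n_pores_in_cell < 1:
        raise InvalidGeometryError("need at least one pore in the cell")
    if n_occluded < 0 or n_occluded >= n_pores_in_cell:
        raise InvalidGeometryError(
            "occluded count must satisfy 0 <= k < n (all pores blocked leaves "
            "no flow path)"
        )
    return n_pores_in_cell / (n_pores_in_cell - n_occluded)
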