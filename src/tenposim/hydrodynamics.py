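"""Fluid velocity in and around a pore: fast semi-analytic composite field.

The unit cell assigned to one pore is a cylinder of radius
``(π · pore_density)^(-1/2)`` with a zero-shear symmetry boundary standing
in for the periodic pore lattice.  The field is built from a Stokes stream
function Ψ = −(Q/2π)·S(ρ, z), where S is the fraction of the per-pore flux
Q enclosed inside radius ρ, so mass conservation through every horizontal
plane is exact by construction:

* above the membrane — orifice-drainage (Sampson-type) convergence,
  normalized so the unit-cell boundary is a streamline and the far field
  is uniform inflow;
* inside the pore channel — the drainage mouth profile (semicircular)
  blended into a parabolic Poiseuille profile over one pore radius;
* a clog is an annular constriction of the channel: the clean stream
  function with its radial coordinate squeezed so the open area matches
  the sphere's blocked cross-section, flux conserved.

No-slip holds exactly on the membrane and pore wall (tangential speed
vanishes at least quadratically at the surfaces).  Velocities come from
the stream function by compact finite differences, so the discrete field
inherits the exact flux bookkeeping.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .device_model import DeviceGeometry, FlowCondition


class OutsideDomainError(ValueError):
    """Velocity requested outside the unit-cell domain."""


@dataclass(frozen=True)
class ClogSpec:
    """Spherical clog lodged on the pore rim, protruding into the lumen.

    ``clog_radius`` is the sphere radius (e.g. 400 nm or 800 nm); the
    sphere sits on the pore edge with its diameter protruding into the
    lumen, blocking an azimuthal patch over heights |z| < clog_radius.
    For the axisymmetric flow the patch becomes a flux-equivalent annular
    constriction at the wall: open radius b(z) with π(c² − b²) equal to
    the sphere's full cross-section π·s(z)² at that height.
    """

    clog_radius: float

    def __post_init__(self):
        if self.clog_radius < 0:
            raise ValueError("clog radius must be non-negative")

    def open_radius(self, z, pore_radius: float):
        """Constricted open radius b(z) of the pore at height z."""
        R = self.clog_radius
        z = np.asarray(z, dtype=float)
        s2 = np.clip(R**2 - z**2, 0.0, None)  # sphere cross-section radius²
        b2 = pore_radius**2 - s2
        if np.any(b2 <= 0):
            raise ValueError("clog occludes the entire pore")
        return np.sqrt(b2)


class SemiAnalyticPoreFlow:
    """Composite stream-function velocity field of one pore's unit cell.

    Domain: ρ ∈ [0, R_cell], z ∈ [−pore_length, z_top] with z = 0 the
    membrane top surface and flow in −z.  ``velocity_cyl`` evaluates
    (u_ρ, u_z) vectorized; ``velocity`` is the checked 3-vector interface.
    """

    def __init__(self, geometry: DeviceGeometry, flow: FlowCondition,
                 clog: ClogSpec | None = None, z_top: float | None = None):
        self.geometry = geometry
        self.flow = flow
        self.clog = clog
        c = geometry.pore_radius
        self.c = c
        self.R_cell = geometry.unit_cell_radius
        self.L = geometry.pore_length
        self.z_top = max(3.5e-6, 2 * geometry.pore_diameter) if z_top is None else z_top
        self.per_pore_flux = flow.per_pore_flux(geometry)
        self.mean_velocity = self.per_pore_flux / geometry.pore_area
        self.entrance_length = 0.22 * c  # slowest Stokes entrance eigenmode
        if clog is not None and clog.clog_radius >= c:
            raise ValueError("clog radius must be smaller than the pore radius")

    # -- stream function ----------------------------------------------------
    def _eta(self, rho, z):
        """Oblate-spheroidal η for an orifice of radius c (uses |z|)."""
        c = self.c
        z = np.abs(z)
        p = rho**2 + z**2 - c**2
        v = (-p + np.sqrt(p * p + 4.0 * c * c * z * z)) / (2.0 * c * c)
        return np.sqrt(np.clip(v, 0.0, 1.0))

    def _s_drain(self, rho, z):
        """Enclosed-flux fraction of the orifice drainage field."""
        return 1.0 - self._eta(rho, z) ** 3

    def _s_mouth(self, rho):
        x2 = np.clip(1.0 - (rho / self.c) ** 2, 0.0, 1.0)
        return 1.0 - x2**1.5

    def _s_pois(self, rho):
        x2 = np.clip((rho / self.c) ** 2, 0.0, 1.0)
        return x2 * (2.0 - x2)

    def _s_clean(self, rho, z):
        rho = np.clip(rho, 0.0, None)
        z = np.asarray(z, dtype=float)
        up = z >= 0.0
        out = np.empty(np.broadcast(rho, z).shape)
        rho_b, z_b = np.broadcast_arrays(rho, z)
        if np.any(up):
            r_, z_ = rho_b[up], z_b[up]
            denom = self._s_drain(np.full_like(z_, self.R_cell), z_)
            out[up] = np.minimum(self._s_drain(r_, z_) / denom, 1.0)
        dn = ~up
        if np.any(dn):
            r_, z_ = rho_b[dn], z_b[dn]
            # fore-aft symmetric profile development: the mouth profile
            # relaxes to parabolic with the slowest Papkovich–Fadle decay
            # length (≈ 0.22 pore radii) and un-develops toward the exit
            ell = self.entrance_length
            h = (1.0 - np.exp(z_ / ell)) * (1.0 - np.exp(-(z_ + self.L) / ell))
            h = np.clip(h, 0.0, 1.0)
            out[dn] = (1.0 - h) * self._s_mouth(r_) + h * self._s_pois(r_)
        return out

    def stream_fraction(self, rho, z):
        """S(ρ, z): fraction of the per-pore flux enclosed inside ρ."""
        if self.clog is None:
            return self._s_clean(rho, z)
        R = self.clog.clog_radius
        z = np.asarray(z, dtype=float)
        rho = np.asarray(rho, dtype=float)
        rho_b, z_b = np.broadcast_arrays(rho, z)
        squeeze = np.abs(z_b) < R
        out = self._s_clean(rho_b, z_b)
        if np.any(squeeze):
            b = self.clog.open_radius(z_b[squeeze], self.c)
            out[squeeze] = self._s_clean(rho_b[squeeze] * self.c / b, z_b[squeeze])
        return out

    # -- velocities ---------------------------------------------------------
    def velocity_cyl(self, rho, z, hr: float = 0.5e-9, hz: float = 0.5e-9):
        """(u_ρ, u_z) at (ρ, z); vectorized, axis-safe, clamped to domain.

        u_z = −(Q/2π)(1/ρ)∂S/∂ρ evaluated as 2·Q/2π·ΔS/Δ(ρ²) (regular on
        the axis), u_ρ = (Q/2π)(1/ρ)∂S/∂z.
        """
        Q = self.per_pore_flux
        if Q == 0.0:
            shape = np.broadcast(np.asarray(rho), np.asarray(z)).shape
            return np.zeros(shape), np.zeros(shape)
        rho = np.clip(np.asarray(rho, dtype=float), 0.0, self.R_cell)
        z = np.clip(np.asarray(z, dtype=float), -self.L, self.z_top)
        rp = rho + hr
        rm = np.clip(rho - hr, 0.0, None)
        dS = self.stream_fraction(rp, z) - self.stream_fraction(rm, z)
        u_z = -(Q / math.pi) * dS / (rp**2 - rm**2)
        dSz = self.stream_fraction(rho, z + hz) - self.stream_fraction(rho, z - hz)
        with np.errstate(divide="ignore", invalid="ignore"):
            u_rho = (Q / (2.0 * math.pi)) * dSz / (2.0 * hz) / rho
        u_rho = np.where(rho < 2.0 * hr, 0.0, u_rho)
        return u_rho, u_z

    def velocity(self, position) -> np.ndarray:
        """Velocity 3-vector at Cartesian (x, y, z); errors outside domain."""
        x, y, z = np.asarray(position, dtype=float)
        rho = math.hypot(x, y)
        if rho > self.R_cell * (1 + 1e-12) or z < -self.L - 1e-15 or z > self.z_top * (1 + 1e-12):
            raise OutsideDomainError(
                f"position (ρ={rho:.3g}, z={z:.3g}) outside unit cell "
                f"(R_cell={self.R_cell:.3g}, z ∈ [{-self.L:.3g}, {self.z_top:.3g}])"
            )
        ur, uz = self.velocity_cyl(rho, z)
        ur, uz = float(ur), float(uz)
        if rho > 0:
            return np.array([ur * x / rho, ur * y / rho, uz])
        return np.array([0.0, 0.0, uz])

    # -- diagnostics --------------------------------------------------------
    def flux_through_plane(self, z: float, n_quad: int = 2000) -> float:
        """|flux| through the horizontal plane at z, by quadrature (m³/s)."""
        rho = np.linspace(0.0, self.R_cell, n_quad)
        _, uz = self.velocity_cyl(rho, np.full_like(rho, z))
        return abs(np.trapezoid(uz * 2.0 * math.pi * rho, rho))

    def max_pore_speed(self, n_rho: int = 80, n_z: int = 160) -> float:
        """Maximum fluid speed inside the pore (full (ρ, z) scan)."""
        rho = np.linspace(0.0, self.c * (1 - 1e-6), n_rho)
        z = np.linspace(-self.L, 0.5 * self.c, n_z)
        RR, ZZ = np.meshgrid(rho, z, indexing="ij")
        ur, uz = self.velocity_cyl(RR.ravel(), ZZ.ravel())
        return float(np.max(np.hypot(ur, uz)))


def semi_analytic_velocity(position, geometry: DeviceGeometry,
                           flow: FlowCondition) -> np.ndarray:
    """Velocity 3-vector of the clean composite field (convenience)."""
    return SemiAnalyticPoreFlow(geometry, flow).velocity(position)


def clogged_velocity_perturbation(geometry: DeviceGeometry, flow: FlowCondition,
                                  clog: ClogSpec) -> SemiAnalyticPoreFlow:
    """Composite field with the clog's annular constriction, flux conserved."""
    return SemiAnalyticPoreFlow(geometry, flow, clog=clog)
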