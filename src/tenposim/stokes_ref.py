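"""Axisymmetric Stokes reference solver on a staggered (r, z) grid.

Independent numerical oracle for the composite semi-analytic field and for
the pore's hydraulic resistance.  Solves steady Stokes flow

    µ ∇² u = ∇p,   ∇·u = 0

in the cylindrical unit cell of one pore (uniform inflow at the top,
uniform outflow at the bottom, zero-shear symmetry at the lateral
boundary, no-slip on the membrane/pore/clog surfaces via a staircase solid
mask) as one sparse saddle-point system, factorized directly.  Second
order in the interior; wall placement is first order (half-cell), which is
ample for the 2–15 % validation tolerances it serves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .device_model import DeviceGeometry, FlowCondition
from .hydrodynamics import ClogSpec


class SolverError(RuntimeError):
    """Raised when the discrete Stokes system cannot be solved cleanly."""


@dataclass
class StokesSolution:
    """Discrete velocity/pressure field with linear interpolation access."""

    geometry: DeviceGeometry
    flow: FlowCondition
    r_faces: np.ndarray      # (nr+1,) radial face positions
    z_faces: np.ndarray      # (nz+1,) axial face positions
    u: np.ndarray            # (nr+1, nz) radial velocity at r-faces
    w: np.ndarray            # (nr, nz+1) axial velocity at z-faces
    p: np.ndarray            # (nr, nz) pressure at cell centers
    solid: np.ndarray        # (nr, nz) cell-centered solid mask
    residual: float

    @property
    def r_centers(self):
        return 0.5 * (self.r_faces[:-1] + self.r_faces[1:])

    @property
    def z_centers(self):
        return 0.5 * (self.z_faces[:-1] + self.z_faces[1:])

    def _interp(self, grid_r, grid_z, values, rho, z):
        rho = np.clip(np.asarray(rho, float), grid_r[0], grid_r[-1])
        z = np.clip(np.asarray(z, float), grid_z[0], grid_z[-1])
        i = np.clip(np.searchsorted(grid_r, rho) - 1, 0, grid_r.size - 2)
        j = np.clip(np.searchsorted(grid_z, z) - 1, 0, grid_z.size - 2)
        tr = (rho - grid_r[i]) / (grid_r[i + 1] - grid_r[i])
        tz = (z - grid_z[j]) / (grid_z[j + 1] - grid_z[j])
        return ((1 - tr) * (1 - tz) * values[i, j]
                + tr * (1 - tz) * values[i + 1, j]
                + (1 - tr) * tz * values[i, j + 1]
                + tr * tz * values[i + 1, j + 1])

    def velocity_cyl(self, rho, z):
        """(u_ρ, u_z) by bilinear interpolation of the staggered fields."""
        ur = self._interp(self.r_faces, self.z_centers, self.u, rho, z)
        uz = self._interp(self.r_centers, self.z_faces, self.w, rho, z)
        return ur, uz

    def flux_through_plane(self, z: float) -> float:
        """|flux| through the plane at z, from the staggered w field."""
        j = int(np.clip(np.searchsorted(self.z_faces, z), 0, self.z_faces.size - 1))
        rc = self.r_centers
        dr = np.diff(self.r_faces)
        return abs(float(np.sum(self.w[:, j] * 2 * math.pi * rc * dr)))

    def pressure_drop(self, z_hi: float | None = None, z_lo: float | None = None) -> float:
        """Area-averaged pressure difference between two planes (Pa)."""
        zc = self.z_centers
        j_hi = -2 if z_hi is None else int(np.argmin(np.abs(zc - z_hi)))
        j_lo = 1 if z_lo is None else int(np.argmin(np.abs(zc - z_lo)))
        rc = self.r_centers
        dr = np.diff(self.r_faces)

        def mean_p(j):
            fluid = ~self.solid[:, j]
            wgt = (rc * dr)[fluid]
            return float(np.sum(self.p[fluid, j] * wgt) / np.sum(wgt))

        return mean_p(j_hi) - mean_p(j_lo)


class StokesVelocityField:
    """Tracking-ready view of a discrete Stokes solution.

    Stokes flow is linear in the flux, so one factorized solution serves
    every flow rate of the same geometry via the ``scale`` factor.
    """

    def __init__(self, solution: StokesSolution, scale: float = 1.0,
                 z_top: float | None = None):
        self.solution = solution
        self.scale = scale
        self.z_top = solution.z_faces[-1] if z_top is None else z_top

    def velocity_cyl(self, rho, z):
        ur, uz = self.solution.velocity_cyl(rho, z)
        return self.scale * ur, self.scale * uz

    def rescaled(self, flow: FlowCondition) -> "StokesVelocityField":
        q0 = self.solution.flow.per_pore_flux(self.solution.geometry)
        q1 = flow.per_pore_flux(self.solution.geometry)
        return StokesVelocityField(self.solution, scale=q1 / q0, z_top=self.z_top)


def solve_axisymmetric_stokes(
    geometry: DeviceGeometry,
    flow: FlowCondition,
    clog: ClogSpec | None = None,
    nr: int = 96,
    nz: int = 192,
    z_top: float | None = None,
    z_bottom: float | None = None,
    residual_tol: float = 1e-8,
) -> StokesSolution:
    """Solve the unit-cell Stokes problem; returns a discrete VelocityField.

    The membrane (film + backing) occupies z ∈ [−pore_length, 0] at
    ρ > pore_radius; an optional clog adds its flux-equivalent annular
    constriction to the solid mask.  Raises :class:`SolverError` if the
    factorization fails or the scaled momentum/continuity residual exceeds
    ``residual_tol``.
    """
    c = geometry.pore_radius
    L = geometry.pore_length
    R = geometry.unit_cell_radius
    mu = flow.dynamic_viscosity
    if z_top is None:
        z_top = max(3.5e-6, 2 * geometry.pore_diameter)
    if z_bottom is None:
        z_bottom = -L - max(3.5e-6, 2 * geometry.pore_diameter)

    r_faces = np.linspace(0.0, R, nr + 1)
    z_faces = np.linspace(z_bottom, z_top, nz + 1)
    dr = r_faces[1] - r_faces[0]
    dz = z_faces[1] - z_faces[0]
    rc = 0.5 * (r_faces[:-1] + r_faces[1:])
    zc = 0.5 * (z_faces[:-1] + z_faces[1:])

    RC, ZC = np.meshgrid(rc, zc, indexing="ij")
    solid = (RC > c) & (ZC > -L) & (ZC < 0.0)
    if clog is not None:
        if clog.clog_radius >= c:
            raise ValueError("clog occludes the entire pore")
        band = np.abs(ZC) < clog.clog_radius
        b = np.where(band, clog.open_radius(np.where(band, ZC, 0.0), c), np.inf)
        solid |= band & (RC > b) & (ZC < 0.0)

    q_pore = flow.per_pore_flux(geometry)
    w_in = q_pore / (math.pi * R**2)  # uniform superficial speed, downward

    n_u = (nr + 1) * nz
    n_w = nr * (nz + 1)
    n_p = nr * nz

    def iu(i, j):
        return i * nz + j

    def iw(i, j):
        return n_u + i * (nz + 1) + j

    def ip(i, j):
        return n_u + n_w + i * nz + j

    rows, cols, vals, rhs = [], [], [], np.zeros(n_u + n_w + n_p)

    def add(r, c_, v):
        rows.append(r)
        cols.append(c_)
        vals.append(v)

    cell_solid = solid  # alias

    def is_solid(i, j):
        if i < 0 or i >= nr or j < 0 or j >= nz:
            return False
        return bool(cell_solid[i, j])

    # -- u momentum (radial) at r-faces ------------------------------------
    for i in range(nr + 1):
        r = r_faces[i]
        for j in range(nz):
            row = iu(i, j)
            if i == 0 or i == nr:
                add(row, row, 1.0)  # axis symmetry / outer wall: u = 0
                continue
            if is_solid(i - 1, j) or is_solid(i, j):
                add(row, row, 1.0)  # face on or in solid
                continue
            # viscous: (1/r) d/dr (r du/dr) − u/r² + d²u/dz²
            rp, rm = r + 0.5 * dr, r - 0.5 * dr
            add(row, iu(i + 1, j), mu * rp / (r * dr * dr))
            add(row, iu(i - 1, j), mu * rm / (r * dr * dr))
            add(row, row, -mu * (rp + rm) / (r * dr * dr) - mu / r**2)
            diag_z = 0.0
            for j2, ghost in ((j + 1, j == nz - 1), (j - 1, j == 0)):
                if ghost:
                    diag_z += -1.0  # tangential u = 0 at top/bottom: ghost = −u
                elif is_solid(i - 1, j2) or is_solid(i, j2):
                    diag_z += -1.0  # no-slip wall between cells: ghost = −u
                else:
                    add(row, iu(i, j2), mu / (dz * dz))
            add(row, row, mu * (diag_z - 2.0) / (dz * dz))
            # pressure gradient
            add(row, ip(i, j), -1.0 / dr)
            add(row, ip(i - 1, j), 1.0 / dr)

    # -- w momentum (axial) at z-faces -------------------------------------
    for i in range(nr):
        r = rc[i]
        for j in range(nz + 1):
            row = iw(i, j)
            if j == 0:
                add(row, row, 1.0)
                rhs[row] = -w_in  # uniform outflow
                continue
            if j == nz:
                add(row, row, 1.0)
                rhs[row] = -w_in  # uniform inflow
                continue
            if is_solid(i, j - 1) or is_solid(i, j):
                add(row, row, 1.0)
                continue
            add(row, iw(i, j + 1), mu / (dz * dz))
            add(row, iw(i, j - 1), mu / (dz * dz))
            add(row, row, -2.0 * mu / (dz * dz))
            diag_r = 0.0
            rp, rm = r + 0.5 * dr, r - 0.5 * dr
            for i2, coef, edge_slip in ((i + 1, rp, i == nr - 1), (i - 1, rm, i == 0)):
                if edge_slip:
                    diag_r += coef  # zero-shear: ghost = w (axis and outer rim)
                elif is_solid(i2, j - 1) or is_solid(i2, j):
                    diag_r += -coef  # no-slip: ghost = −w
                else:
                    add(row, iw(i2, j), mu * coef / (r * dr * dr))
            add(row, row, mu * (diag_r - (rp + rm)) / (r * dr * dr))
            add(row, ip(i, j), -1.0 / dz)
            add(row, ip(i, j - 1), 1.0 / dz)

    # -- continuity per cell ------------------------------------------------
    pinned = False
    for i in range(nr):
        r = rc[i]
        for j in range(nz):
            row = ip(i, j)
            if cell_solid[i, j]:
                add(row, row, 1.0)
                continue
            if not pinned:
                add(row, row, 1.0)  # gauge: fix one fluid pressure to 0
                pinned = True
                continue
            add(row, iu(i + 1, j), r_faces[i + 1] / (r * dr))
            add(row, iu(i, j), -r_faces[i] / (r * dr))
            add(row, iw(i, j + 1), 1.0 / dz)
            add(row, iw(i, j), -1.0 / dz)

    A = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n_u + n_w + n_p,) * 2)
    )
    # row equilibration: scale each equation by its largest coefficient
    row_max = np.maximum(np.abs(A).max(axis=1).toarray().ravel(), 1e-300)
    D = sp.diags(1.0 / row_max)
    try:
        x = spla.spsolve((D @ A).tocsr(), rhs / row_max)
    except Exception as exc:  # pragma: no cover - solver backend failure
        raise SolverError(f"sparse factorization failed: {exc}") from exc
    if not np.all(np.isfinite(x)):
        raise SolverError("non-finite solution (singular system)")

    # componentwise backward error of the equilibrated system
    resid = np.abs(A @ x - rhs) / row_max
    scale = max(float(np.max(np.abs(x))), abs(w_in), 1e-300)
    residual = float(np.max(resid) / scale)
    if residual > residual_tol:
        raise SolverError(f"residual {residual:.2e} exceeds {residual_tol:.0e}")

    u = x[:n_u].reshape(nr + 1, nz)
    w = x[n_u:n_u + n_w].reshape(nr, nz + 1)
    p = x[n_u + n_w:].reshape(nr, nz)
    # normalize the pinned-cell gauge to mean outflow-plane pressure = 0
    return StokesSolution(geometry, flow, r_faces, z_faces, u, w, p, solid, residual)
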