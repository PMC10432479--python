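"""Magnetic field of a saturated NiFe film pierced by a cylindrical pore.

The 200 nm permalloy film saturates along the vertical external field
(µ0·Ms ≈ 0.79 T, i.e. ~7900 G).  A uniformly perpendicular-magnetized
*infinite* sheet produces zero field everywhere (its two charged faces
cancel), so by Babinet superposition the field of a sheet with a circular
hole is

    B(r) = B_ext ẑ − B_disk(r),

where ``B_disk`` is the full field (interior magnetization term included)
of a uniformly magnetized disk that fills the pore.  The disk field is
evaluated as the field of its equivalent surface current — a short
solenoid of sheet current Ms on the pore wall — by quadrature of circular
current loops, whose field is a classic elliptic-integral closed form.
This representation is smooth across the (virtual) disk faces, which lie
in the open pore mouth where particles travel.

Coordinates: z = 0 at the film *top* surface, z positive against the flow;
the film occupies −t ≤ z ≤ 0 at ρ larger than the pore radius.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.interpolate import RegularGridInterpolator
from scipy.special import ellipe, ellipk

from .device_model import DeviceGeometry

MU0 = 4e-7 * math.pi  # vacuum permeability, T·m/A

#: Saturation magnetization equivalent of ~7900 G permalloy, A/m.
NIFE_SATURATION = 0.79 / MU0  # ≈ 6.29e5

#: Relative permeability assigned to the film so that µ0·µr·H reproduces
#: the ~7900 G permalloy saturation at the reference drive H = 341 kA/m.
FILM_RELATIVE_PERMEABILITY = 1.844

#: Reference drive field strength, A/m (µ0·H ≈ 0.43 T ≈ the 0.4 T headline).
REFERENCE_APPLIED_H = 341_000.0


def demag_limited_magnetization(b_external: float = 0.4,
                                mu_r: float = FILM_RELATIVE_PERMEABILITY) -> float:
    """Perpendicular magnetization (A/m) of a thin linear-µ film.

    A film magnetized along its normal carries a demagnetizing field equal
    to its own magnetization, so M = χ/(1+χ) · H with χ = µr − 1; M can
    never exceed the applied H itself.  With the default µr this gives
    µ0·M ≈ 0.18 T at 0.4 T drive — far below the material's ~0.79 T
    saturation, which is unreachable in this geometry.
    """
    chi = mu_r - 1.0
    if chi < 0:
        raise ValueError("relative permeability must be >= 1")
    return chi / (1.0 + chi) * b_external / MU0


#: Canonical effective film magnetization (A/m) under the 0.4 T drive.
FILM_EFFECTIVE_MAGNETIZATION = demag_limited_magnetization()  # ≈ 1.457e5


class PositionInFilmError(ValueError):
    """Field requested inside the solid magnetic film."""


@dataclass(frozen=True)
class MagneticEnvironment:
    """External drive and film magnetization model.

    ``b_external`` is the uniform vertical flux density of the NdFeB
    magnet (default 0.4 T).  The film is uniformly magnetized along +z
    with ``film_saturation``; all other layers have unit relative
    permeability.  The default magnetization is the demagnetization-
    limited value of a linear-permeability film (µr ≈ 1.84 calibrated
    against the ~7900 G permalloy saturation at 341 kA/m); the fully
    saturated material value is available via :meth:`saturated`.
    """

    b_external: float = 0.4
    film_saturation: float = FILM_EFFECTIVE_MAGNETIZATION

    def __post_init__(self):
        if self.b_external <= 0:
            raise ValueError("external field must be positive")
        if self.film_saturation < 0:
            raise ValueError("film saturation must be non-negative")

    @classmethod
    def saturated(cls, b_external: float = 0.4) -> "MagneticEnvironment":
        """Fully saturated film (µ0·M ≈ 0.79 T), ignoring shape demagnetization."""
        return cls(b_external=b_external, film_saturation=NIFE_SATURATION)

    @classmethod
    def from_applied_h(cls, applied_h: float = REFERENCE_APPLIED_H,
                       mu_r: float = FILM_RELATIVE_PERMEABILITY) -> "MagneticEnvironment":
        """Drive stated as a field strength H (A/m): B = µ0·H, film demag-limited."""
        b = MU0 * applied_h
        return cls(b_external=b,
                   film_saturation=demag_limited_magnetization(b, mu_r))


# ---------------------------------------------------------------------------
# closed-form primitives


def disk_axial_field(ms: float, radius: float, thickness: float, z) -> np.ndarray:
    """On-axis Bz of a uniformly axially magnetized cylinder (closed form).

    The cylinder is centered on the origin (midplane z = 0, faces at
    ±thickness/2).  Valid inside and outside; even in z; decays as the
    dipole |z|⁻³ far away.
    """
    if radius <= 0 or thickness <= 0:
        raise ValueError("radius and thickness must be positive")
    z = np.asarray(z, dtype=float)
    h = 0.5 * thickness
    up = (z + h) / np.sqrt((z + h) ** 2 + radius**2)
    dn = (z - h) / np.sqrt((z - h) ** 2 + radius**2)
    return 0.5 * MU0 * ms * (up - dn)


def _loop_field(rho, dz, radius):
    """(Bρ, Bz) per unit current of a circular loop of given radius.

    Field point at cylindrical (rho, dz) relative to the loop plane.
    Standard elliptic-integral form; the on-axis limit is handled
    explicitly.  Singular only on the wire itself.
    """
    rho = np.asarray(rho, dtype=float)
    dz = np.asarray(dz, dtype=float)
    a = radius
    q = (a + rho) ** 2 + dz**2
    m = 4.0 * a * rho / q
    K = ellipk(m)
    E = ellipe(m)
    denom = (a - rho) ** 2 + dz**2
    pref = MU0 / (2.0 * np.pi * np.sqrt(q))
    bz = pref * (K + E * (a**2 - rho**2 - dz**2) / denom)
    with np.errstate(divide="ignore", invalid="ignore"):
        brho = pref * (dz / rho) * (-K + E * (a**2 + rho**2 + dz**2) / denom)
    on_axis = rho < 1e-15 * a
    if np.any(on_axis):
        brho = np.where(on_axis, 0.0, brho)
        bz_axis = MU0 * a**2 / (2.0 * (a**2 + dz**2) ** 1.5)
        bz = np.where(on_axis, bz_axis, bz)
    return brho, bz


def _end_refined_nodes(thickness: float, n_levels: int = 11, n_gauss: int = 6):
    """Quadrature nodes/weights over z' ∈ [−t, 0], refined toward both ends.

    The solenoid sheet ends at z' = 0 and z' = −t are where the integrand
    peaks for field points near the rim corners, so panels shrink
    geometrically toward both ends (smallest panel ≈ t/2^n_levels).
    """
    x, w = leggauss(n_gauss)
    edges = [0.0]
    acc = 0.0
    for k in range(1, n_levels):
        acc += 0.5 ** k
        edges.append(acc)
    edges.append(1.0)  # covers the remaining middle
    edges = np.asarray(edges) * 0.5  # [0, 0.5], mirrored below
    half = np.concatenate([edges, 1.0 - edges[::-1][1:]])
    nodes, weights = [], []
    for lo, hi in zip(half[:-1], half[1:]):
        mid, rad = 0.5 * (lo + hi), 0.5 * (hi - lo)
        nodes.append(mid + rad * x)
        weights.append(rad * w)
    nodes = np.concatenate(nodes) * thickness - thickness  # z' in [−t, 0]
    weights = np.concatenate(weights) * thickness
    return nodes, weights


def magnetized_disk_field(rho, z, radius: float, thickness: float, ms: float,
                          nodes=None, weights=None):
    """(Bρ, Bz) of a uniformly magnetized disk occupying z ∈ [−t, 0].

    Exact equivalent-solenoid quadrature: sheet current Ms φ̂ on ρ = radius.
    Interior magnetization contribution is included automatically, so the
    Babinet subtraction is valid at every point off the current sheet.
    """
    shp = np.broadcast(np.asarray(rho), np.asarray(z)).shape
    if ms == 0.0:
        return np.zeros(shp), np.zeros(shp)
    if nodes is None:
        nodes, weights = _end_refined_nodes(thickness)
    rho = np.asarray(rho, dtype=float)
    z = np.asarray(z, dtype=float)
    rho_b, z_b = np.broadcast_arrays(rho, z)
    dz = z_b.reshape(-1, 1) - nodes.reshape(1, -1)
    rr = np.repeat(rho_b.reshape(-1, 1), nodes.size, axis=1)
    brho_n, bz_n = _loop_field(rr, dz, radius)
    brho = ms * (brho_n @ weights)
    bz = ms * (bz_n @ weights)
    return brho.reshape(shp), bz.reshape(shp)


# ---------------------------------------------------------------------------
# pore field


class PoreField:
    """B field of the pierced film under the uniform external drive.

    ``b_cyl`` is the direct (quadrature) evaluator used by the tests and
    for building cached tables; :class:`FieldTable` is the fast
    interpolating path used by particle tracking.
    """

    def __init__(self, env: MagneticEnvironment, geometry: DeviceGeometry):
        self.env = env
        self.geometry = geometry
        self._nodes, self._weights = _end_refined_nodes(geometry.nife_thickness)

    # -- geometry helpers ---------------------------------------------------
    def _in_film(self, rho, z) -> np.ndarray:
        t = self.geometry.nife_thickness
        c = self.geometry.pore_radius
        return (rho >= c) & (z <= 0.0) & (z >= -t)

    # -- direct evaluation --------------------------------------------------
    def b_cyl(self, rho, z, check: bool = True):
        """(Bρ, Bz) at cylindrical (ρ, z); vectorized.

        Raises :class:`PositionInFilmError` for points inside the film
        solid when ``check`` is true.
        """
        rho = np.asarray(rho, dtype=float)
        z = np.asarray(z, dtype=float)
        if check and np.any(self._in_film(rho, z)):
            raise PositionInFilmError("field requested inside the magnetic film")
        brho_d, bz_d = magnetized_disk_field(
            rho, z, self.geometry.pore_radius, self.geometry.nife_thickness,
            self.env.film_saturation, self._nodes, self._weights,
        )
        return -brho_d, self.env.b_external - bz_d

    def pore_field(self, position) -> np.ndarray:
        """B 3-vector at a Cartesian position (x, y, z); axisymmetric."""
        x, y, z = np.asarray(position, dtype=float)
        rho = math.hypot(x, y)
        brho, bz = self.b_cyl(rho, z)
        brho = float(brho)
        if rho > 0:
            return np.array([brho * x / rho, brho * y / rho, float(bz)])
        return np.array([0.0, 0.0, float(bz)])

    def b_squared(self, rho, z, check: bool = True):
        brho, bz = self.b_cyl(rho, z, check=check)
        return brho**2 + bz**2

    def grad_b_squared_cyl(self, rho, z, step: float = 0.5e-9, check: bool = True):
        """(∂ρ|B|², ∂z|B|²) by central differences with sub-nm step."""
        rho = np.asarray(rho, dtype=float)
        z = np.asarray(z, dtype=float)
        if check and np.any(self._in_film(rho, z)):
            raise PositionInFilmError("gradient requested inside the magnetic film")
        gr = (self.b_squared(np.abs(rho + step), z, check=False)
              - self.b_squared(np.abs(rho - step), z, check=False)) / (2 * step)
        gz = (self.b_squared(rho, z + step, check=False)
              - self.b_squared(rho, z - step, check=False)) / (2 * step)
        return gr, gz

    def grad_B_squared(self, position) -> np.ndarray:
        """∇|B|² 3-vector at a Cartesian position."""
        x, y, z = np.asarray(position, dtype=float)
        rho = math.hypot(x, y)
        gr, gz = self.grad_b_squared_cyl(rho, z)
        gr, gz = float(gr), float(gz)
        if rho > 0:
            return np.array([gr * x / rho, gr * y / rho, gz])
        return np.array([0.0, 0.0, gz])


def _tiered_axis(segments, offset=0.0):
    """Concatenate (lo, hi, n) linspace tiers into a strictly increasing axis."""
    parts = []
    for lo, hi, n in segments:
        parts.append(np.linspace(lo, hi, n, endpoint=False))
    parts.append(np.array([segments[-1][1]]))
    axis = np.concatenate(parts) + offset
    return np.unique(axis)


class FieldTable:
    """Cached (ρ, z) tables of B and ∇|B|² for fast trajectory work.

    A nonuniform rectilinear grid resolves the rim neighbourhood at
    ``fine_step`` (2 nm default) over a band of half-width
    min(d, ``fine_span``) around the pore wall and the film, with coarse
    tiers elsewhere.  Gradients are differentiated on the grid
    (second-order, nonuniform-aware) and interpolated linearly.
    """

    def __init__(self, env: MagneticEnvironment, geometry: DeviceGeometry,
                 z_top: float | None = None, z_bottom: float | None = None,
                 fine_step: float = 2e-9, fine_span: float = 0.6e-6,
                 chunk: int = 40_000):
        self.env = env
        self.geometry = geometry
        c = geometry.pore_radius
        d = geometry.pore_diameter
        t = geometry.nife_thickness
        if z_top is None:
            z_top = max(3.5e-6, 2 * d)
        if z_bottom is None:
            z_bottom = -geometry.pore_length
        self.z_top, self.z_bottom = z_top, z_bottom
        rho_max = 1.02 * max(geometry.unit_cell_radius, math.sqrt(2.0) * d)
        span = min(d, fine_span)
        # sub-nm offset keeps nodes off the virtual disk faces and wall
        off = 0.137e-9
        rho_lo, rho_hi = max(c - span, 0.0), c + span
        rho_segments = []
        if rho_lo > 0:
            rho_segments.append((0.0, rho_lo, max(24, int(rho_lo / 40e-9))))
        n_fine = int((rho_hi - rho_lo) / fine_step)
        rho_segments.append((rho_lo, rho_hi, n_fine))
        rho_segments.append((rho_hi, rho_max, 64))
        self.rho_axis = _tiered_axis(rho_segments, offset=off)
        self.rho_axis[0] = 0.0
        z_lo, z_hi = -t - span, span
        z_fine_step = 2 * fine_step
        z_segments = [(z_bottom, z_lo, 48),
                      (z_lo, z_hi, int((z_hi - z_lo) / z_fine_step)),
                      (z_hi, z_top, 80)]
        self.z_axis = _tiered_axis(z_segments, offset=off)
        self.z_axis[0] = z_bottom
        self.z_axis[-1] = z_top

        pf = PoreField(env, geometry)
        nr, nz = self.rho_axis.size, self.z_axis.size
        RR, ZZ = np.meshgrid(self.rho_axis, self.z_axis, indexing="ij")
        brho = np.empty((nr, nz))
        bz = np.empty((nr, nz))
        flat_r, flat_z = RR.ravel(), ZZ.ravel()
        for i0 in range(0, flat_r.size, chunk):
            sl = slice(i0, min(i0 + chunk, flat_r.size))
            br, bv = pf.b_cyl(flat_r[sl], flat_z[sl], check=False)
            brho.ravel()[sl] = br
            bz.ravel()[sl] = bv
        b2 = brho**2 + bz**2
        g_rho = np.gradient(b2, self.rho_axis, axis=0, edge_order=2)
        g_z = np.gradient(b2, self.z_axis, axis=1, edge_order=2)
        pts = (self.rho_axis, self.z_axis)
        kw = dict(bounds_error=False, fill_value=None)
        self._i_brho = RegularGridInterpolator(pts, brho, **kw)
        self._i_bz = RegularGridInterpolator(pts, bz, **kw)
        self._i_grho = RegularGridInterpolator(pts, g_rho, **kw)
        self._i_gz = RegularGridInterpolator(pts, g_z, **kw)

    def _stack(self, rho, z):
        rho = np.clip(np.asarray(rho, dtype=float), 0.0, self.rho_axis[-1])
        z = np.clip(np.asarray(z, dtype=float), self.z_axis[0], self.z_axis[-1])
        shape = np.broadcast(rho, z).shape
        return np.stack(np.broadcast_arrays(rho, z), axis=-1), shape

    def b_cyl(self, rho, z):
        p, shape = self._stack(rho, z)
        return self._i_brho(p).reshape(shape), self._i_bz(p).reshape(shape)

    def grad_b_squared_cyl(self, rho, z):
        p, shape = self._stack(rho, z)
        return self._i_grho(p).reshape(shape), self._i_gz(p).reshape(shape)
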