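"""Static oil-aqueous equilibrium and retina-tamponade contact.

A lighter-than-water silicone-oil (SiO) bubble floats on the residual aqueous
in the vitreous chamber.  Its equilibrium shape is set by gravity and by the
oil-aqueous interfacial tension — not by viscosity — so a single solve per
(posture, fill fraction) serves both oil grades.

The interface is restricted to a two-member family: planes normal to gravity
and spheres whose center lies on the gravity line through the chamber
centroid.  The family is exact in the zero-Bond (pure capillary: spherical
cap meeting the wall) and infinite-Bond (flat stratification) limits; at the
Bond number of this system, Bo = (Δρ) g R^2 / σ ≈ 0.64, the energy-minimizing
member interpolates between them.  Total energy per configuration:

    E = σ A_interface + σ cosθ A_wet_oil  −  Δρ g ∫ z dV_oil

with θ the static contact angle measured through the aqueous phase (the
aqueous wets the retina; the oil-side convention flips the wall-term sign),
z the height along the anti-gravity direction.  All volumes and moments are
evaluated by exact radial integration over the star-shaped chamber, one ray
per mesh triangle.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .geometry import (
    ANTERIOR,
    HEMISPHERES,
    REGIONS,
    RETINA_REGIONS,
    SUPERIOR,
    EyeGeometry,
    label_points,
    split_samples,
)

GRAVITY = 9.81  # m/s^2


class SolverError(RuntimeError):
    """Raised when the constrained interface search cannot be completed."""


class DegenerateRegionError(ValueError):
    """Raised when a contact fraction is requested for a zero-area region."""


@dataclass(frozen=True)
class FluidPair:
    """Oil-aqueous property set.  Defaults: medical-grade PDMS vs aqueous.

    Viscosities are dynamic [mPa·s]; densities [kg/m^3]; interfacial tension
    [N/m]; contact angles [deg] at the oil-aqueous-retina line, measured
    through the phase named by ``contact_angle_convention``.  The advancing
    and receding angles bound contact-line hysteresis during motion; the
    static solver uses only the static angle.
    """

    oil_density: float = 980.0
    aqueous_density: float = 1000.0
    oil_viscosity: float = 1000.0
    aqueous_viscosity: float = 1.0
    interfacial_tension: float = 0.044
    static_contact_angle: float = 16.2
    advancing_contact_angle: float = 21.2
    receding_contact_angle: float = 11.2
    contact_angle_convention: str = "aqueous"

    def __post_init__(self) -> None:
        if not (self.receding_contact_angle <= self.static_contact_angle <= self.advancing_contact_angle):
            raise ValueError("contact angles must satisfy receding <= static <= advancing")
        if self.oil_density <= 0 or self.aqueous_density <= 0:
            raise ValueError("densities must be positive")
        if self.oil_density >= self.aqueous_density:
            raise ValueError("oil must be lighter than aqueous")
        if self.contact_angle_convention not in ("aqueous", "oil"):
            raise ValueError("contact_angle_convention must be 'aqueous' or 'oil'")

    @property
    def density_difference(self) -> float:
        return self.aqueous_density - self.oil_density

    def with_viscosity(self, oil_viscosity: float) -> "FluidPair":
        return replace(self, oil_viscosity=oil_viscosity)


SIO1000 = FluidPair(oil_viscosity=1000.0)
SIO5000 = FluidPair(oil_viscosity=5000.0)


@dataclass(frozen=True)
class Posture:
    """Head posture as a gravity direction in the anatomical frame."""

    name: str
    gravity: np.ndarray

    def __post_init__(self) -> None:
        g = np.asarray(self.gravity, dtype=float)
        object.__setattr__(self, "gravity", g / np.linalg.norm(g))

    @property
    def up(self) -> np.ndarray:
        return -self.gravity

    @staticmethod
    def standing() -> "Posture":
        return Posture("standing", -SUPERIOR)

    @staticmethod
    def tilt45() -> "Posture":
        return Posture("tilt45", -(SUPERIOR + ANTERIOR) / np.sqrt(2.0))

    @staticmethod
    def supine() -> "Posture":
        return Posture("supine", -ANTERIOR)

    @staticmethod
    def from_name(name: str) -> "Posture":
        try:
            return getattr(Posture, name)()
        except AttributeError:
            raise ValueError(f"unknown posture {name!r}") from None


POSTURES = ("standing", "tilt45", "supine")


# ---------------------------------------------------------------------------
# interface family
# ---------------------------------------------------------------------------
class PlanarInterface:
    """Flat interface: oil occupies { x : x·up >= offset }."""

    kind = "plane"

    def __init__(self, up: np.ndarray, offset: float):
        self.up = np.asarray(up, dtype=float)
        self.offset = float(offset)

    def oil_side(self, points: np.ndarray) -> np.ndarray:
        return points @ self.up >= self.offset - 1e-9

    def ray_intervals(self, dirs: np.ndarray, radii: np.ndarray):
        c = dirs @ self.up
        a = np.zeros_like(radii)
        b = radii.copy()
        pos = c > 1e-15
        neg = c < -1e-15
        flat = ~pos & ~neg
        a[pos] = np.clip(self.offset / c[pos], 0.0, radii[pos])
        b[neg] = np.clip(self.offset / c[neg], 0.0, radii[neg])
        b[flat] = np.where(self.offset <= 0.0, radii[flat], 0.0)
        return [(a, b)]


class SphericalInterface:
    """Spherical-cap interface: oil occupies { x : side·(|x−c| − ρ) >= 0 }."""

    kind = "sphere"

    def __init__(self, center: np.ndarray, radius: float, side: int):
        self.center = np.asarray(center, dtype=float)
        self.radius = float(radius)
        self.side = int(side)

    def oil_side(self, points: np.ndarray) -> np.ndarray:
        d = np.linalg.norm(points - self.center, axis=-1)
        return self.side * (d - self.radius) >= -1e-9

    def ray_intervals(self, dirs: np.ndarray, radii: np.ndarray):
        bh = dirs @ self.center
        disc = bh * bh - (self.center @ self.center - self.radius**2)
        hit = disc > 0.0
        sq = np.sqrt(np.maximum(disc, 0.0))
        tlo = np.clip(bh - sq, 0.0, radii)
        thi = np.clip(bh + sq, 0.0, radii)
        tlo[~hit] = 0.0
        thi[~hit] = 0.0
        if self.side < 0:  # oil inside the sphere
            return [(tlo, thi)]
        zeros = np.zeros_like(radii)
        return [(zeros, tlo), (thi, radii.copy())]


def _perpendicular(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e = np.cross(v, w)
    return e / np.linalg.norm(e)


# ---------------------------------------------------------------------------
# radial quadrature over the star-shaped chamber
# ---------------------------------------------------------------------------
class RayQuadrature:
    """One radial ray per surface triangle; exact per-ray segment volumes.

    The chamber is star-shaped about the eye center, so its volume decomposes
    into cones over the triangles.  A fluid region bounded by a plane or
    sphere cuts each ray into closed-form segments, giving volumes and height
    moments that converge with mesh resolution and are exactly consistent
    (full occupation reproduces the mesh volume).
    """

    def __init__(self, geom: EyeGeometry):
        tri = geom.mesh.triangles
        self.tet_volumes = np.abs(np.einsum("ij,ij->i", tri[:, 0], np.cross(tri[:, 1], tri[:, 2]))) / 6.0
        centroids = geom.mesh.triangles_center
        self.dirs = centroids / np.linalg.norm(centroids, axis=1)[:, None]
        self.radii = geom.radius_function(self.dirs)
        self.total_volume = float(self.tet_volumes.sum())
        self._geom = geom

    def oil_volume(self, interface) -> float:
        """Oil volume [mm^3] on the oil side of the interface.

        Planes are handled by exact polyhedral slicing (radial rays lying in
        the interface plane would make the quadrature discontinuous in the
        plane offset); spheres by the radial quadrature, which is continuous
        in the sphere parameters.
        """
        if interface.kind == "plane":
            return self._plane_volume(interface)
        frac = np.zeros_like(self.radii)
        r3 = self.radii**3
        for a, b in interface.ray_intervals(self.dirs, self.radii):
            frac += (b**3 - a**3) / r3
        return float(np.sum(self.tet_volumes * frac))

    def _plane_volume(self, interface: "PlanarInterface") -> float:
        # V_above = ∮ max(x·up − h, 0) (up·n) dA over the closed wall
        # (divergence theorem with F = up·max(s, 0); exact for the polyhedron
        # after analytic clipping of the plane-crossing triangles).
        up, h = interface.up, interface.offset
        mesh = self._geom.mesh
        s = mesh.vertices @ up - h
        sf = s[mesh.faces]  # (nf, 3)
        tri = mesh.triangles
        un = 0.5 * np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]) @ up  # (up·n̂)·A
        full = np.einsum("ij->i", sf) / 3.0  # ∫ s dA / A over the whole triangle

        n_pos = (sf > 0.0).sum(axis=1)
        contrib = np.where(n_pos == 3, un * full, 0.0)
        for k in (1, 2):  # triangles with k vertices on the oil side
            m = n_pos == k
            if not np.any(m):
                continue
            svals = np.sort(sf[m], axis=1)  # ascending: negatives first
            if k == 1:
                sp, sn1, sn2 = svals[:, 2], svals[:, 0], svals[:, 1]
                ratio = (sp / (sp - sn1)) * (sp / (sp - sn2))
                contrib[m] = un[m] * ratio * sp / 3.0
            else:
                sn, sp1, sp2 = svals[:, 0], svals[:, 1], svals[:, 2]
                ratio = (sn / (sn - sp1)) * (sn / (sn - sp2))
                contrib[m] = un[m] * ((sp1 + sp2 + sn) / 3.0 - ratio * sn / 3.0)
        return float(contrib.sum())

    def oil_height_moment(self, interface, up: np.ndarray) -> float:
        """∫ z dV over the oil [mm^4], z measured along ``up`` from the eye center."""
        m = np.zeros_like(self.radii)
        r3 = self.radii**3
        for a, b in interface.ray_intervals(self.dirs, self.radii):
            m += 0.75 * (b**4 - a**4) / r3
        cosz = self.dirs @ up
        return float(np.sum(self.tet_volumes * cosz * m))

    def contains(self, points: np.ndarray) -> np.ndarray:
        r = np.linalg.norm(points, axis=-1)
        safe = np.where(r > 1e-12, r, 1.0)
        wall = self._geom.radius_function(points / safe[:, None])
        return r < wall - 1e-9


# ---------------------------------------------------------------------------
# equilibrium state
# ---------------------------------------------------------------------------
@dataclass
class EquilibriumState:
    """Solved interface with the per-vertex oil-wetting map."""

    posture: Posture
    fill_requested: float
    fill_achieved: float
    interface: object
    wet: np.ndarray  # bool per vertex: True = in contact with oil
    mode: str  # "flat" | "capillary"
    energy: float | None = None  # J, capillary mode only


def _solve_plane_offset(quad: RayQuadrature, up: np.ndarray, fill: float, tol: float) -> PlanarInterface:
    proj = quad._geom.vertices @ up
    lo, hi = float(proj.min()) - 1.0, float(proj.max()) + 1.0
    target = fill * quad.total_volume

    def f(h: float) -> float:
        return quad.oil_volume(PlanarInterface(up, h)) - target

    if f(lo) <= 0.0:  # full fill (up to round-off): whole chamber is oil
        return PlanarInterface(up, lo)
    h = brentq(f, lo, hi, xtol=1e-9 * (hi - lo), maxiter=200)
    iface = PlanarInterface(up, h)
    if abs(quad.oil_volume(iface) / quad.total_volume - fill) > max(tol, 1e-6):
        raise SolverError("plane positioning failed to meet the volume constraint")
    return iface


def solve_flat_interface(
    geom: EyeGeometry, fill: float, posture: Posture, tol: float = 1e-4
) -> EquilibriumState:
    """Zero-surface-tension equilibrium: flat interface normal to gravity.

    The plane offset is found by root bracketing so that the oil volume above
    it equals ``fill`` times the chamber volume within ``tol``.
    """
    if not 0.0 < fill <= 1.0:
        raise ValueError("fill must lie in (0, 1]")
    quad = RayQuadrature(geom)
    iface = _solve_plane_offset(quad, posture.up, fill, tol)
    wet = iface.oil_side(geom.vertices)
    return EquilibriumState(
        posture=posture,
        fill_requested=fill,
        fill_achieved=quad.oil_volume(iface) / quad.total_volume,
        interface=iface,
        wet=wet,
        mode="flat",
    )


def _refine_crossings(point_fn, inside, s_grid, contains, n_bisect: int = 30) -> np.ndarray:
    """Column-wise measure of the inside set along a parameter grid.

    ``inside`` is the (ns, ncol) mask of ``contains(point_fn(s, col))`` on the
    coarse grid; every transition between consecutive samples is localized by
    vectorized bisection, giving per-column inside-lengths in the parameter.
    """
    ns, ncol = inside.shape
    ds = s_grid[1] - s_grid[0]
    lengths = inside[:-1].astype(float) * 0.0
    both = inside[:-1] & inside[1:]
    lengths[both] = ds
    trans = inside[:-1] != inside[1:]
    ti, tj = np.nonzero(trans)
    if len(ti):
        lo = np.full(len(ti), 0.0)
        hi = np.full(len(ti), ds)
        base = s_grid[ti]
        for _ in range(n_bisect):
            mid = 0.5 * (lo + hi)
            pts = point_fn(base + mid, tj)
            mid_in = contains(pts)
            # move toward the boundary: keep the side whose state differs
            same_as_lower = mid_in == inside[ti, tj]
            lo = np.where(same_as_lower, mid, lo)
            hi = np.where(same_as_lower, hi, mid)
        cross = base + 0.5 * (lo + hi)
        # measure of inside part of each transition cell
        seg = np.where(inside[ti, tj], cross - base, base + ds - cross)
        np.add.at(lengths, (ti, tj), seg)
    return lengths.sum(axis=0)


def _interface_area(iface, quad: RayQuadrature, nphi: int = 256, ncoarse: int = 96) -> float:
    """Area [mm^2] of the interface lying inside the chamber.

    Deterministic column quadrature: for a sphere, uniform-in-area bands
    (Archimedes) in the local z; for a plane, polar columns about the axis
    point.  Column/chamber crossings are bisection-refined, so the error is
    set by the azimuthal discretization only (<0.1% of the chamber area).
    """
    phis = (np.arange(nphi) + 0.5) * (2.0 * np.pi / nphi)
    if iface.kind == "plane":
        e1 = _perpendicular(iface.up)
        e2 = np.cross(iface.up, e1)
        extent = 1.3 * float(quad.radii.max())
        origin = iface.up * iface.offset
        rad = np.cos(phis)[:, None] * e1 + np.sin(phis)[:, None] * e2  # (nphi, 3)

        def point_fn(r, cols):
            return origin + r[:, None] * rad[cols]

        s_grid = np.linspace(0.0, extent, ncoarse)
        pts = origin + s_grid[:, None, None] * rad[None, :, :]
        inside = quad.contains(pts.reshape(-1, 3)).reshape(ncoarse, nphi)
        # ∫ r dr per column: bisect crossings of r, weight each inside cell by r̄
        ds = s_grid[1] - s_grid[0]
        # use fine midpoint rule with refined boundaries via r-weighted measure:
        # approximate ∫ r dr over inside set as Σ r_mid · (inside length); with
        # bisected boundaries the residual error is O(ds²) per column.
        lengths = _refine_crossings(point_fn, inside, s_grid, quad.contains)
        # r-weight: centroid of the inside set per column (recompute cheaply)
        mids = 0.5 * (s_grid[:-1] + s_grid[1:])
        w = (inside[:-1] & inside[1:]) * mids[:, None] * ds
        trans = inside[:-1] != inside[1:]
        # transition cells: weight by cell midpoint (error O(ds²))
        w = w.sum(axis=0)
        frac_len = lengths - ((inside[:-1] & inside[1:]) * ds).sum(axis=0)
        tcell_mid = (trans * mids[:, None]).sum(axis=0) / np.maximum(trans.sum(axis=0), 1)
        w += frac_len * tcell_mid
        return float(w.sum() * (2.0 * np.pi / nphi))

    rho, center = iface.radius, iface.center
    ez = np.array([0.0, 0.0, 1.0])
    e1 = _perpendicular(ez)
    e2 = np.cross(ez, e1)
    cphi, sphi = np.cos(phis), np.sin(phis)

    def point_fn(z, cols):
        rr = np.sqrt(np.maximum(rho * rho - z * z, 0.0))
        return center + np.column_stack(
            [rr * cphi[cols], rr * sphi[cols], z]
        )

    s_grid = np.linspace(-rho, rho, ncoarse)
    rr = np.sqrt(np.maximum(rho * rho - s_grid * s_grid, 0.0))
    pts = (
        center
        + np.stack(
            [rr[:, None] * cphi[None, :], rr[:, None] * sphi[None, :], np.broadcast_to(s_grid[:, None], (ncoarse, nphi))],
            axis=-1,
        )
    )
    inside = quad.contains(pts.reshape(-1, 3)).reshape(ncoarse, nphi)
    lengths = _refine_crossings(point_fn, inside, s_grid, quad.contains)
    # Archimedes: dA = rho dz dphi
    return float(rho * lengths.sum() * (2.0 * np.pi / nphi))


def _apparent_contact_cosine(iface, eye_radius: float) -> float | None:
    """cos of the apparent contact angle (through the aqueous) at the eye wall.

    The contact curve of a plane or of a sphere centered anywhere with the
    spherical eye wall is a circle along which the apparent angle is uniform.
    Returns None when the interface does not intersect the eye sphere.
    """
    R = eye_radius
    if iface.kind == "plane":
        if abs(iface.offset) >= R:
            return None
        return -iface.offset / R
    d = float(np.linalg.norm(iface.center))
    rho = iface.radius
    if not abs(R - rho) < d < R + rho:
        return None
    c = (R * R - d * d + rho * rho) / (2.0 * R * rho)
    return c if iface.side < 0 else -c


def _is_admissible(iface, geom: EyeGeometry, fluids: FluidPair) -> bool:
    """Contact-line admissibility: reject members whose apparent angle is on
    the over-wetted side of the static angle.

    An apparent angle below the static one (aqueous convention) would make
    the oil contact line advance spontaneously, so such members are not
    static equilibria; they are exactly the near-degenerate "film" members
    of the spherical family.  With the oil-side convention the inequality
    flips.  The bound is evaluated at the eye-sphere wall; the lens contact
    line is not constrained.
    """
    cos_app = _apparent_contact_cosine(iface, geom.eye_radius)
    if cos_app is None:
        return True
    theta_aq = fluids.static_contact_angle
    if fluids.contact_angle_convention == "oil":
        theta_aq = 180.0 - theta_aq
        return cos_app >= np.cos(np.radians(theta_aq)) - 1e-9
    return cos_app <= np.cos(np.radians(theta_aq)) + 1e-9


def _configuration_energy(
    iface, quad: RayQuadrature, geom: EyeGeometry, fluids: FluidPair, up: np.ndarray
) -> float:
    """Total capillary + gravitational energy [J] of a volume-feasible interface."""
    sigma = fluids.interfacial_tension
    theta = np.radians(fluids.static_contact_angle)
    wall_sign = 1.0 if fluids.contact_angle_convention == "aqueous" else -1.0
    a_int = _interface_area(iface, quad) * 1e-6
    pts, areas = split_samples(geom, 1)
    a_wet = float(areas[iface.oil_side(pts)].sum()) * 1e-6
    mz = quad.oil_height_moment(iface, up) * 1e-12
    return sigma * a_int + wall_sign * sigma * np.cos(theta) * a_wet - fluids.density_difference * GRAVITY * mz


def _sphere_candidates(
    quad: RayQuadrature, axis_point: np.ndarray, up: np.ndarray, kappa: float, fill: float
) -> list[SphericalInterface]:
    """Volume-feasible spheres of signed curvature ``kappa`` with center on the gravity line."""
    rho = 1.0 / abs(kappa)
    side = 1 if kappa > 0 else -1
    target = fill * quad.total_volume
    rmax = float(quad.radii.max())
    zgrid = np.linspace(-(rmax + rho) - 2.0, rmax + rho + 2.0, 96)

    def vol(z: float) -> float:
        return quad.oil_volume(SphericalInterface(axis_point + z * up, rho, side))

    vals = np.array([vol(z) for z in zgrid]) - target
    out: list[SphericalInterface] = []
    for i in np.nonzero(np.diff(np.sign(vals)) != 0)[0]:
        if vals[i] == 0.0:
            z = zgrid[i]
        else:
            z = brentq(lambda zz: vol(zz) - target, zgrid[i], zgrid[i + 1], xtol=1e-8 * rmax)
        out.append(SphericalInterface(axis_point + z * up, rho, side))
    return out


def solve_capillary_interface(
    geom: EyeGeometry,
    fill: float,
    posture: Posture,
    fluids: FluidPair = FluidPair(),
    tol: float = 1e-4,
    n_kappa: int = 45,
    min_radius_factor: float = 0.25,
) -> EquilibriumState:
    """Energy-minimizing interface from the plane-or-sphere family.

    Scans signed curvature κ (κ>0: oil outside the sphere; κ<0: oil inside;
    κ=0: plane), solving the volume constraint for each member by root
    bracketing along the gravity line, then polishes the best κ by staged
    grid refinement.  Members violating contact-line admissibility (apparent
    wall angle on the over-wetted side of the static angle) are excluded.
    Reduces to :func:`solve_flat_interface` as σ→0.
    """
    if not 0.0 < fill <= 1.0:
        raise ValueError("fill must lie in (0, 1]")
    quad = RayQuadrature(geom)
    up = posture.up
    axis_point = np.asarray(geom.mesh.center_mass, dtype=float)
    if fill >= 1.0 - 1e-12:
        iface = _solve_plane_offset(quad, up, fill, tol)
        return EquilibriumState(posture, fill, 1.0, iface, np.ones(len(geom.vertices), bool), "capillary")

    kmax = 1.0 / (min_radius_factor * geom.eye_radius)

    # buoyant stability: the oil must occupy the uppermost point of the
    # chamber (an inverted arrangement is Rayleigh-Taylor unstable, however
    # its wall energy compares)
    top_point = geom.vertices[np.argmax(geom.vertices @ up)][None, :]

    def best_for_kappa(kappa: float) -> tuple[float, object]:
        if abs(kappa) < 1e-9:
            cands = [_solve_plane_offset(quad, up, fill, tol)]
        else:
            cands = _sphere_candidates(quad, axis_point, up, kappa, fill)
        cands = [
            c
            for c in cands
            if _is_admissible(c, geom, fluids) and bool(c.oil_side(top_point)[0])
        ]
        if not cands:
            return np.inf, None
        energies = [_configuration_energy(c, quad, geom, fluids, up) for c in cands]
        k = int(np.argmin(energies))
        return energies[k], cands[k]

    def refine(kappas: np.ndarray) -> tuple[np.ndarray, list, int]:
        scan = [best_for_kappa(k) for k in kappas]
        energies = np.array([e for e, _ in scan])
        return energies, scan, int(np.argmin(energies))

    kappas = np.linspace(-kmax, kmax, n_kappa)
    if not np.any(np.abs(kappas) < 1e-12):
        kappas = np.sort(np.append(kappas, 0.0))
    energies, scan, ibest = refine(kappas)
    if not np.any(np.isfinite(energies)):
        raise SolverError(
            f"no volume-feasible interface found (fill={fill}, posture={posture.name})"
        )
    e_ref, iface = scan[ibest]
    for _ in range(2):  # staged grid refinement around the running best
        lo = kappas[max(ibest - 1, 0)]
        hi = kappas[min(ibest + 1, len(kappas) - 1)]
        kappas = np.linspace(lo, hi, 17)
        energies, scan, ibest = refine(kappas)
        if np.isfinite(energies[ibest]) and energies[ibest] < e_ref:
            e_ref, iface = scan[ibest]
    achieved = quad.oil_volume(iface) / quad.total_volume
    if abs(achieved - fill) > max(tol, 5e-4):
        raise SolverError(
            f"volume constraint violated: achieved {achieved:.5f} vs requested {fill:.5f}"
        )
    return EquilibriumState(
        posture=posture,
        fill_requested=fill,
        fill_achieved=achieved,
        interface=iface,
        wet=iface.oil_side(geom.vertices),
        mode="capillary",
        energy=float(e_ref),
    )


# ---------------------------------------------------------------------------
# closed-form supine (axisymmetric) coverage
# ---------------------------------------------------------------------------
def _flat_cap_ratio(fill: float) -> float:
    """Solve x^2 (3 − x) = 4·fill for the oil-cap height ratio x = h/R."""
    return brentq(lambda x: x * x * (3.0 - x) - 4.0 * fill, 0.0, 2.0, xtol=1e-14)


def analytic_supine_coverage(
    fill: float,
    eye_radius: float = 12.0,
    contact_angle: float | None = None,
    interfacial_tension: float = 0.044,
    density_difference: float = 20.0,
) -> float:
    """Closed-form oil-covered wall fraction for a lens-free sphere, supine.

    Flat variant (``contact_angle`` None): the interface is horizontal and
    the covered fraction is x/2 where x solves x²(3−x) = 4·fill.

    Capillary variant: the axisymmetric counterpart of the mesh solver,
    evaluated entirely from spherical-cap closed forms.  The oil region is a
    wall cap above the contact circle (polar angle β from the anti-gravity
    pole) plus a downward-bulging spherical-cap meniscus; for each β the
    meniscus sphere is fixed by the volume constraint, and β minimizes

        E(β) = σ A_meniscus + σ cosθ A_wall_cap − Δρ g ∫ z dV_oil,

    θ measured through the aqueous.  Members whose apparent wall angle falls
    below θ (over-wetted "film" members, which are not static equilibria of
    a free contact line) are excluded, exactly as in the mesh solver.
    Covered fraction = (1 − cos β)/2.  No mesh is involved.
    """
    if not 0.0 < fill < 1.0:
        raise ValueError("fill must lie in (0, 1)")
    if contact_angle is None:
        return 0.5 * _flat_cap_ratio(fill)

    R = eye_radius
    theta = np.radians(contact_angle)
    sigma = interfacial_tension
    v_target = fill * (4.0 / 3.0) * np.pi * R**3
    beta_flat = np.arccos(1.0 - _flat_cap_ratio(fill))

    def wall_cap(beta: float) -> tuple[float, float, float]:
        """(volume, area, z-moment) of the container cap above the circle."""
        z0 = R * np.cos(beta)
        h = R - z0
        v = np.pi * h * h * (3.0 * R - h) / 3.0
        zbar = 3.0 * (2.0 * R - h) ** 2 / (4.0 * (3.0 * R - h))
        return v, 2.0 * np.pi * R * h, v * zbar

    def solve_meniscus(beta: float) -> tuple[float, float, float]:
        """Meniscus sphere (center height c, radius rho, cap height h2) at β."""
        z0 = R * np.cos(beta)
        a = R * np.sin(beta)
        v1 = wall_cap(beta)[0]

        def vol_residual(c: float) -> float:
            rho = np.hypot(a, c - z0)
            h2 = rho - (c - z0)
            return v1 + np.pi * h2 * h2 * (3.0 * rho - h2) / 3.0 - v_target

        hi = z0 + 1e5 * R
        if vol_residual(hi) >= 0.0:  # β at the flat limit: vanishing meniscus
            c = hi
        else:
            c = brentq(vol_residual, z0 - 50.0 * R, hi, xtol=1e-11 * R)
        rho = np.hypot(a, c - z0)
        return c, rho, rho - (c - z0)

    def energy(beta: float) -> float:
        v1, a_wall, m1 = wall_cap(beta)
        if v1 > v_target:  # wall cap alone exceeds the oil volume
            return np.inf
        c, rho, h2 = solve_meniscus(beta)
        # contact-line admissibility at the wall circle
        cos_app = (R * R - c * c + rho * rho) / (2.0 * R * rho)
        if cos_app > np.cos(theta) + 1e-9:
            return np.inf
        a_men = 2.0 * np.pi * rho * h2
        v2 = np.pi * h2 * h2 * (3.0 * rho - h2) / 3.0
        zbar2 = c - 3.0 * (2.0 * rho - h2) ** 2 / (4.0 * (3.0 * rho - h2))
        mz = (m1 + v2 * zbar2) * 1e-12  # mm^4 -> m^4
        return (
            sigma * a_men * 1e-6
            + sigma * np.cos(theta) * a_wall * 1e-6
            - density_difference * GRAVITY * mz
        )

    betas = np.linspace(np.radians(1.0), beta_flat, 257)
    es = np.array([energy(b) for b in betas])
    ib = int(np.argmin(es))
    for _ in range(3):  # staged grid refinement around the running best
        lo, hi = betas[max(ib - 1, 0)], betas[min(ib + 1, len(betas) - 1)]
        betas = np.linspace(lo, hi, 33)
        es = np.array([energy(b) for b in betas])
        ib = int(np.argmin(es))
    return 0.5 * (1.0 - np.cos(float(betas[ib])))


# ---------------------------------------------------------------------------
# contact fractions
# ---------------------------------------------------------------------------
def contact_fractions(state: EquilibriumState, geom: EyeGeometry, split_depth: int = 2) -> pd.DataFrame:
    """Oil-wetted area fraction per (region, hemisphere), plus aggregates.

    Columns: posture, fill, region, hemisphere, area_mm2, wetted_area_mm2,
    fraction.  Rows cover every present region × {superior, inferior, both}
    and the ``retina`` aggregate (macula + post- + pre-equatorial); the ora
    band and lens are reported but excluded from the retina denominator.
    Areas use barycentric splitting (4**split_depth samples per face) with
    wetness evaluated at each sub-centroid against the solved interface.
    """
    pts, areas = split_samples(geom, split_depth)
    tr, th = label_points(geom, pts)
    wet_t = state.interface.oil_side(pts)

    def one(region_ids: list[int], hemi: int | None) -> tuple[float, float]:
        m = np.isin(tr, region_ids)
        if hemi is not None:
            m &= th == hemi
        return float(areas[m].sum()), float(areas[m & wet_t].sum())

    rows = []
    groups: list[tuple[str, list[int]]] = [(r, [REGIONS.index(r)]) for r in REGIONS]
    groups.append(("retina", [REGIONS.index(r) for r in RETINA_REGIONS]))
    for rname, rids in groups:
        for hname, hid in (("superior", 0), ("inferior", 1), ("both", None)):
            area, wetted = one(rids, hid)
            if area == 0.0:
                if rname in RETINA_REGIONS or rname == "retina":
                    raise DegenerateRegionError(f"region {rname}/{hname} has zero area")
                continue
            rows.append(
                {
                    "posture": state.posture.name,
                    "fill": state.fill_requested,
                    "region": rname,
                    "hemisphere": hname,
                    "area_mm2": area,
                    "wetted_area_mm2": wetted,
                    "fraction": wetted / area,
                }
            )
    return pd.DataFrame(rows)


def contact_fraction(state: EquilibriumState, geom: EyeGeometry, region: str, hemisphere: str = "both") -> float:
    """Single oil-contact fraction for one region/hemisphere."""
    df = contact_fractions(state, geom)
    row = df[(df.region == region) & (df.hemisphere == hemisphere)]
    if row.empty:
        raise DegenerateRegionError(f"region {region}/{hemisphere} not present")
    return float(row.fraction.iloc[0])
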