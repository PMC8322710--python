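"""Vitreous-chamber surface geometry and anatomical segmentation.

The chamber wall is modeled as a sphere (default diameter 24 mm) indented
anteriorly by the posterior surface of the crystalline lens, itself a sphere
whose center sits outside the globe on the anterior axis.  The resulting
closed surface is star-shaped about the eye center, which lets every
downstream volume computation work on radial rays.

Anatomical frame (fixed to the eye, not to gravity):

* ``ANTERIOR`` = +z (posterior pole at -z),
* ``SUPERIOR`` = +y,
* ``NASAL``    = +x.

Wall regions, by polar angle measured at the eye center from the anterior
axis (anterior pole = 0 deg, posterior pole = 180 deg):

* ``lens``           — the indentation surface itself,
* ``ora``            — annulus between the lens rim and ``ora_limit_angle``,
* ``preequatorial``  — (``ora_limit_angle``, 90 deg],
* ``postequatorial`` — (90 deg, 180 deg - ``macula_half_angle``),
* ``macula``         — posterior cap of half-angle ``macula_half_angle``.

``macula + postequatorial + preequatorial`` together constitute the retina;
the ora band and the lens are reported separately and excluded from
retina-contact denominators.  Each region is further split into superior and
inferior halves by the sign of the superior coordinate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

ANTERIOR = np.array([0.0, 0.0, 1.0])
SUPERIOR = np.array([0.0, 1.0, 0.0])
NASAL = np.array([1.0, 0.0, 0.0])

REGIONS = ("macula", "postequatorial", "preequatorial", "ora", "lens")
RETINA_REGIONS = ("macula", "postequatorial", "preequatorial")
HEMISPHERES = ("superior", "inferior")


class GeometryError(ValueError):
    """Raised for invalid lens/globe configurations or broken meshes."""


@dataclass
class EyeGeometry:
    """Triangulated chamber wall with per-vertex anatomical labels.

    Lengths are millimetres throughout.  ``vertex_region`` holds indices into
    :data:`REGIONS`; ``vertex_hemisphere`` holds 0 for superior, 1 for
    inferior.  Labels are filled by :func:`segment_regions`.
    """

    eye_radius: float
    lens_radius: float | None
    lens_center_offset: float | None
    mesh: trimesh.Trimesh
    vertex_region: np.ndarray | None = None
    vertex_hemisphere: np.ndarray | None = None
    macula_half_angle: float | None = None
    ora_limit_angle: float | None = None
    anterior_axis: np.ndarray = field(default_factory=lambda: ANTERIOR.copy())
    superior_axis: np.ndarray = field(default_factory=lambda: SUPERIOR.copy())

    @property
    def vertices(self) -> np.ndarray:
        return self.mesh.vertices

    @property
    def triangles(self) -> np.ndarray:
        return self.mesh.faces

    @property
    def has_lens(self) -> bool:
        return self.lens_radius is not None

    @property
    def lens_rim_angle(self) -> float:
        """Polar angle [deg] of the lens-indentation rim, from the anterior axis."""
        if not self.has_lens:
            return 0.0
        R, r, d = self.eye_radius, self.lens_radius, self.lens_center_offset
        return float(np.degrees(np.arccos((R * R + d * d - r * r) / (2.0 * R * d))))

    def polar_angle_deg(self, points: np.ndarray | None = None) -> np.ndarray:
        """Polar angle from the anterior axis [deg] of points (default: vertices)."""
        p = self.vertices if points is None else np.atleast_2d(points)
        c = (p @ self.anterior_axis) / np.linalg.norm(p, axis=-1)
        return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))

    def radius_function(self, directions: np.ndarray) -> np.ndarray:
        """Analytic chamber radius along unit directions from the eye center."""
        return chamber_radius(
            np.atleast_2d(directions),
            self.eye_radius,
            self.lens_radius,
            self.lens_center_offset,
            self.anterior_axis,
        )

    def region_mask(self, region: str, hemisphere: str = "both") -> np.ndarray:
        """Boolean vertex mask for a region name (or the ``retina`` aggregate)."""
        if self.vertex_region is None:
            raise GeometryError("mesh has not been segmented; call segment_regions")
        if region == "retina":
            wanted = [REGIONS.index(r) for r in RETINA_REGIONS]
            mask = np.isin(self.vertex_region, wanted)
        elif region == "all":
            mask = np.ones(len(self.vertices), dtype=bool)
        else:
            if region not in REGIONS:
                raise GeometryError(f"unknown region {region!r}")
            mask = self.vertex_region == REGIONS.index(region)
        if hemisphere != "both":
            if hemisphere not in HEMISPHERES:
                raise GeometryError(f"unknown hemisphere {hemisphere!r}")
            mask = mask & (self.vertex_hemisphere == HEMISPHERES.index(hemisphere))
        return mask

    def vertex_areas(self) -> np.ndarray:
        """Barycentric (one-third) vertex areas [mm^2]; sums to the mesh area."""
        va = np.zeros(len(self.vertices))
        np.add.at(va, self.mesh.faces.ravel(), np.repeat(self.mesh.area_faces / 3.0, 3))
        return va


def _hemisphere_codes(points: np.ndarray, superior_axis: np.ndarray) -> np.ndarray:
    """0 = superior, 1 = inferior by the superior coordinate; points exactly on
    the dividing plane are tie-broken by the nasal coordinate so that
    symmetric bands split evenly instead of all counting as superior."""
    y = points @ superior_axis
    x = points @ NASAL
    return np.where(y > 0.0, 0, np.where(y < 0.0, 1, np.where(x >= 0.0, 0, 1))).astype(np.int8)


def chamber_radius(
    directions: np.ndarray,
    eye_radius: float,
    lens_radius: float | None,
    lens_center_offset: float | None,
    anterior_axis: np.ndarray = ANTERIOR,
) -> np.ndarray:
    """Distance from the eye center to the chamber wall along unit directions.

    Equals ``eye_radius`` outside the lens rim cone; inside it, the nearer
    intersection of the ray with the lens sphere.
    """
    d = np.atleast_2d(directions)
    r = np.full(len(d), float(eye_radius))
    if lens_radius is None:
        return r
    cos_psi = d @ anterior_axis
    R, rl, off = eye_radius, lens_radius, lens_center_offset
    cos_rim = (R * R + off * off - rl * rl) / (2.0 * R * off)
    inside = cos_psi > cos_rim
    if np.any(inside):
        cp = cos_psi[inside]
        disc = rl * rl - off * off * (1.0 - cp * cp)
        disc = np.maximum(disc, 0.0)
        r[inside] = off * cp - np.sqrt(disc)
    return r


def _subdivisions_for_resolution(eye_radius: float, resolution: float) -> int:
    # icosahedron edge ~ 1.0515 R, halved per subdivision
    subs = int(np.ceil(np.log2(1.0515 * eye_radius / resolution)))
    return int(np.clip(subs, 2, 7))


def build_chamber_mesh(
    eye_radius: float = 12.0,
    lens_radius: float | None = 5.5,
    lens_center_offset: float | None = 13.0,
    resolution: float = 0.45,
) -> EyeGeometry:
    """Build the chamber wall mesh (sphere plus lens indentation).

    Parameters
    ----------
    eye_radius : float
        Globe radius [mm].
    lens_radius, lens_center_offset : float or None
        Lens-sphere radius and its center's distance from the eye center
        along the anterior axis [mm].  ``None`` disables the indentation.
    resolution : float
        Target edge length [mm]; the icosphere subdivision level is chosen to
        approach it.

    The mesh is produced by radially projecting icosphere vertices inside the
    rim cone onto the lens sphere, so it stays watertight by construction.
    """
    if resolution <= 0:
        raise GeometryError("resolution must be positive")
    if (lens_radius is None) != (lens_center_offset is None):
        raise GeometryError("lens_radius and lens_center_offset must be set together")
    if lens_radius is not None:
        if not (abs(lens_center_offset - lens_radius) < eye_radius < lens_center_offset + lens_radius):
            raise GeometryError(
                "lens sphere must intersect the globe without engulfing it"
            )
    subs = _subdivisions_for_resolution(eye_radius, resolution)
    mesh = trimesh.creation.icosphere(subdivisions=subs, radius=1.0)
    dirs = np.asarray(mesh.vertices)
    dirs /= np.linalg.norm(dirs, axis=1)[:, None]
    radii = chamber_radius(dirs, eye_radius, lens_radius, lens_center_offset)
    mesh = trimesh.Trimesh(vertices=dirs * radii[:, None], faces=mesh.faces, process=False)
    if not mesh.is_watertight:
        raise GeometryError("chamber mesh is not watertight")
    return EyeGeometry(
        eye_radius=eye_radius,
        lens_radius=lens_radius,
        lens_center_offset=lens_center_offset,
        mesh=mesh,
    )


def segment_regions(
    geom: EyeGeometry,
    macula_half_angle: float = 20.0,
    ora_limit_angle: float = 40.0,
) -> EyeGeometry:
    """Label every vertex with a wall region and a hemisphere (in place).

    Angles are polar angles from the anterior axis in degrees.  The macula is
    the posterior cap of half-angle ``macula_half_angle`` centered on the
    posterior pole; the post-/pre-equatorial bands are split at the equator;
    the ora band runs from ``ora_limit_angle`` down to the lens rim.
    """
    psi = geom.polar_angle_deg()
    rim = geom.lens_rim_angle
    if not rim < ora_limit_angle < 90.0:
        raise GeometryError("ora_limit_angle must lie between the lens rim and the equator")
    if not 0.0 < macula_half_angle < 90.0:
        raise GeometryError("macula_half_angle must lie in (0, 90) degrees")

    region = np.full(len(psi), -1, dtype=np.int8)
    region[psi >= 180.0 - macula_half_angle] = REGIONS.index("macula")
    region[(psi > 90.0) & (psi < 180.0 - macula_half_angle)] = REGIONS.index("postequatorial")
    region[(psi > ora_limit_angle) & (psi <= 90.0)] = REGIONS.index("preequatorial")
    region[(psi > rim) & (psi <= ora_limit_angle)] = REGIONS.index("ora")
    if geom.has_lens:
        # lens vertices are the radially projected ones, strictly inside the rim cone
        on_lens = np.linalg.norm(geom.vertices, axis=1) < geom.eye_radius * (1.0 - 1e-9)
        region[on_lens] = REGIONS.index("lens")
        region[(psi <= rim) & ~on_lens] = REGIONS.index("lens")
    else:
        region[psi <= ora_limit_angle] = REGIONS.index("ora")
    if np.any(region < 0):
        raise GeometryError("segmentation left unlabeled vertices")

    hemi = _hemisphere_codes(geom.vertices, geom.superior_axis)
    geom.vertex_region = region
    geom.vertex_hemisphere = hemi
    geom.macula_half_angle = macula_half_angle
    geom.ora_limit_angle = ora_limit_angle
    return geom


def triangle_labels(geom: EyeGeometry) -> tuple[np.ndarray, np.ndarray]:
    """Per-triangle (region, hemisphere) by majority vote of vertex labels.

    Ties (three distinct vertex regions) fall back to the label the triangle
    centroid would receive.
    """
    if geom.vertex_region is None:
        raise GeometryError("mesh has not been segmented")
    faces = geom.mesh.faces
    vr = geom.vertex_region[faces]  # (nf, 3)
    vh = geom.vertex_hemisphere[faces]

    def majority(vals: np.ndarray, fallback: np.ndarray) -> np.ndarray:
        out = np.where(vals[:, 1] == vals[:, 2], vals[:, 1], vals[:, 0])
        tie = (vals[:, 0] != vals[:, 1]) & (vals[:, 1] != vals[:, 2]) & (vals[:, 0] != vals[:, 2])
        out[tie] = fallback[tie]
        return out

    centroids = geom.mesh.triangles_center
    psi_c = geom.polar_angle_deg(centroids)
    fb_region = np.full(len(faces), REGIONS.index("preequatorial"), dtype=np.int8)
    fb_region[psi_c >= 180.0 - geom.macula_half_angle] = REGIONS.index("macula")
    fb_region[(psi_c > 90.0) & (psi_c < 180.0 - geom.macula_half_angle)] = REGIONS.index("postequatorial")
    fb_region[(psi_c > geom.lens_rim_angle) & (psi_c <= geom.ora_limit_angle)] = REGIONS.index("ora")
    if geom.has_lens:
        fb_region[psi_c <= geom.lens_rim_angle] = REGIONS.index("lens")
    fb_hemi = np.where(centroids @ geom.superior_axis >= 0.0, 0, 1).astype(np.int8)
    return majority(vr, fb_region), majority(vh, fb_hemi)


_BARY_CACHE: dict[int, np.ndarray] = {}


def _barycentric_centroids(depth: int) -> np.ndarray:
    """Centroids (in barycentric coordinates) of the 4**depth congruent
    sub-triangles of midpoint subdivision, shape (4**depth, 3)."""
    if depth not in _BARY_CACHE:
        tris = np.array([[[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]]])
        for _ in range(depth):
            a, b, c = tris[:, 0], tris[:, 1], tris[:, 2]
            ab, bc, ca = (a + b) / 2, (b + c) / 2, (c + a) / 2
            tris = np.concatenate(
                [
                    np.stack([a, ab, ca], axis=1),
                    np.stack([ab, b, bc], axis=1),
                    np.stack([ca, bc, c], axis=1),
                    np.stack([ab, bc, ca], axis=1),
                ]
            )
        _BARY_CACHE[depth] = tris.mean(axis=1)
    return _BARY_CACHE[depth]


def split_samples(geom: EyeGeometry, depth: int = 2) -> tuple[np.ndarray, np.ndarray]:
    """Sub-triangle sample points and areas for barycentric area accounting.

    Midpoint subdivision of each (planar) face into 4**depth equal-area
    sub-triangles; returns centroids (nf * 4**depth, 3) and the matching
    area weights [mm^2].
    """
    bary = _barycentric_centroids(depth)  # (k, 3)
    tri = geom.mesh.triangles  # (nf, 3, 3)
    pts = np.einsum("kb,fbx->fkx", bary, tri).reshape(-1, 3)
    areas = np.repeat(geom.mesh.area_faces / len(bary), len(bary))
    return pts, areas


def label_points(geom: EyeGeometry, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(region, hemisphere) codes of arbitrary wall-adjacent points, from the
    analytic cone boundaries (lens rim, ora limit, equator, macula edge)."""
    if geom.macula_half_angle is None:
        raise GeometryError("mesh has not been segmented")
    psi = geom.polar_angle_deg(points)
    region = np.full(len(psi), REGIONS.index("preequatorial"), dtype=np.int8)
    region[psi >= 180.0 - geom.macula_half_angle] = REGIONS.index("macula")
    region[(psi > 90.0) & (psi < 180.0 - geom.macula_half_angle)] = REGIONS.index("postequatorial")
    region[(psi > geom.lens_rim_angle) & (psi <= geom.ora_limit_angle)] = REGIONS.index("ora")
    if geom.has_lens:
        region[psi <= geom.lens_rim_angle] = REGIONS.index("lens")
    else:
        region[psi <= geom.ora_limit_angle] = REGIONS.index("ora")
    hemi = _hemisphere_codes(points, geom.superior_axis)
    return region, hemi


def region_areas(geom: EyeGeometry, split_depth: int = 2) -> "pd.DataFrame":
    """Area [mm^2] per (region, hemisphere) by barycentric splitting.

    Each face is split into 4**split_depth equal sub-triangles whose
    centroids are labeled against the analytic region boundaries, so the
    total area is conserved exactly and boundary-band errors shrink as
    4**(-split_depth).
    """
    import pandas as pd

    pts, areas = split_samples(geom, split_depth)
    region, hemi = label_points(geom, pts)
    rows = []
    for ri, rname in enumerate(REGIONS):
        for hi, hname in enumerate(HEMISPHERES):
            rows.append(
                {
                    "region": rname,
                    "hemisphere": hname,
                    "area_mm2": float(areas[(region == ri) & (hemi == hi)].sum()),
                }
            )
    return pd.DataFrame(rows)
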