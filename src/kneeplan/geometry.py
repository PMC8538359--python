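"""Small geometric utilities shared by the femur generator, the spacer
kernel and the planning engine.

Everything works in a right-handed frame in millimetres:
``+z`` proximal (along the mechanical axis of the intact fixture),
``+x`` lateral for a right femur, ``+y`` anterior.
"""

from __future__ import annotations

import math

import numpy as np
import trimesh

from .errors import GeometryError, MeasurementError

__all__ = [
    "unit",
    "round_half_up",
    "ray_cast_first_hit",
    "section_centroid",
    "mirror_mesh_x",
    "disc_samples",
]


def unit(v: np.ndarray) -> np.ndarray:
    """Return ``v`` normalised to unit length; raises on near-zero input."""
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n < 1e-12:
        raise GeometryError("cannot normalise a near-zero vector")
    return v / n


def round_half_up(x: float, step: float = 1.0) -> float:
    """Round to the nearest multiple of ``step``, halves away from zero
    going up (3.5 -> 4 for step 1).  Python's banker's rounding is not what
    surgeons expect when quantising augment thicknesses.
    """
    return math.floor(x / step + 0.5) * step


def disc_samples(radius: float, n_rings: int = 2, n_per_ring: int = 6) -> np.ndarray:
    """Sample points on a disc of ``radius`` in its local (a, b) plane.

    Returns an (N, 2) array including the centre; used to average a gap
    measurement over a small condylar patch instead of a single ray.
    """
    pts = [(0.0, 0.0)]
    for i in range(1, n_rings + 1):
        r = radius * i / n_rings
        for k in range(n_per_ring):
            a = 2.0 * np.pi * k / n_per_ring + (0.5 * np.pi * i / n_rings)
            pts.append((r * np.cos(a), r * np.sin(a)))
    return np.array(pts)


def ray_cast_first_hit(
    mesh: trimesh.Trimesh,
    origins: np.ndarray,
    direction: np.ndarray,
    t_min: float = 1e-6,
) -> np.ndarray:
    """First-hit distances of parallel rays against a triangle mesh.

    A vectorised Moller-Trumbore intersection over all triangles at once;
    the meshes in this package are small (tens of thousands of faces) so an
    acceleration structure is unnecessary.  Returns one distance per ray,
    ``nan`` where a ray misses the mesh entirely.
    """
    origins = np.atleast_2d(np.asarray(origins, dtype=float))
    d = unit(direction)

    tri = mesh.triangles  # (M, 3, 3)
    v0, v1, v2 = tri[:, 0], tri[:, 1], tri[:, 2]
    e1 = v1 - v0
    e2 = v2 - v0
    pvec = np.cross(d, e2)  # (M, 3), same for every ray
    det = np.einsum("ij,ij->i", e1, pvec)
    ok = np.abs(det) > 1e-12
    inv_det = np.where(ok, 1.0 / np.where(ok, det, 1.0), 0.0)

    out = np.full(len(origins), np.nan)
    for i, o in enumerate(origins):
        tvec = o - v0
        u = np.einsum("ij,ij->i", tvec, pvec) * inv_det
        qvec = np.cross(tvec, e1)
        v = (qvec @ d) * inv_det
        t = np.einsum("ij,ij->i", e2, qvec) * inv_det
        hit = ok & (u >= -1e-9) & (v >= -1e-9) & (u + v <= 1 + 1e-9) & (t > t_min)
        if hit.any():
            out[i] = t[hit].min()
    return out


def point_mesh_distance(mesh: trimesh.Trimesh, points: np.ndarray) -> np.ndarray:
    """Unsigned distance from each point to the mesh surface.

    Exact point-to-triangle distance (Eberly's region decomposition),
    vectorised over all faces per query point; adequate for the small
    meshes and few query points used here.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.triangles
    b, e0, e1 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    a = np.einsum("ij,ij->i", e0, e0)
    bb = np.einsum("ij,ij->i", e0, e1)
    c = np.einsum("ij,ij->i", e1, e1)
    det = np.maximum(a * c - bb * bb, 1e-300)

    out = np.empty(len(points))
    for i, p in enumerate(points):
        dvec = b - p
        d = np.einsum("ij,ij->i", e0, dvec)
        e = np.einsum("ij,ij->i", e1, dvec)
        s = np.clip((bb * e - c * d) / det, 0.0, 1.0)
        t = np.clip((bb * d - a * e) / det, 0.0, 1.0)
        # clamp to the triangle: project (s, t) onto s + t <= 1
        over = s + t > 1.0
        if over.any():
            so, to = s[over], t[over]
            # parametrise the hypotenuse and re-minimise
            num = (c[over] + e[over] - bb[over] - d[over])
            den = a[over] - 2 * bb[over] + c[over]
            so = np.clip(num / np.maximum(den, 1e-300), 0.0, 1.0)
            s[over], t[over] = so, 1.0 - so
        # refine edge cases by re-clamping the partner coordinate
        s_fix = np.clip(-(d + bb * t) / np.maximum(a, 1e-300), 0.0, 1.0)
        t_fix = np.clip(-(e + bb * s) / np.maximum(c, 1e-300), 0.0, 1.0)
        cand = np.stack(
            [
                np.stack([s, t], axis=1),
                np.stack([s_fix, np.minimum(t, 1 - s_fix)], axis=1),
                np.stack([np.minimum(s, 1 - t_fix), t_fix], axis=1),
            ]
        )
        best = np.inf
        for st in cand:
            q = b + st[:, :1] * e0 + st[:, 1:2] * e1
            dist2 = np.einsum("ij,ij->i", q - p, q - p)
            best = min(best, dist2.min())
        out[i] = np.sqrt(best)
    return out


def section_centroid(mesh: trimesh.Trimesh, plane_origin, plane_normal) -> np.ndarray:
    """Area centroid of the cross-section of ``mesh`` by a plane.

    The section polygon(s) are assembled by trimesh and measured with
    shapely; multiple loops (e.g. two bones in one slice) are combined by
    area weighting.
    """
    path = mesh.section(plane_origin=plane_origin, plane_normal=plane_normal)
    if path is None or len(path.entities) == 0:
        raise MeasurementError("section plane does not intersect the mesh")
    planar, T = path.to_2D()
    polys = planar.polygons_full
    if len(polys) == 0:
        raise MeasurementError("section produced no closed polygon")
    areas = np.array([p.area for p in polys])
    cents = np.array([[p.centroid.x, p.centroid.y] for p in polys])
    c2 = (cents * areas[:, None]).sum(axis=0) / areas.sum()
    c3 = trimesh.transformations.transform_points([[c2[0], c2[1], 0.0]], T)[0]
    return np.asarray(c3, dtype=float)


def mirror_mesh_x(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    """Reflect a mesh through the sagittal plane (x -> -x), keeping
    outward-facing winding."""
    v = mesh.vertices.copy()
    v[:, 0] *= -1.0
    f = mesh.faces[:, [0, 2, 1]].copy()
    return trimesh.Trimesh(vertices=v, faces=f, process=False)
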