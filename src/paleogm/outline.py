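"""Crown-outline processing for the 2D molar analysis.

Workflow: fit a best-fit plane to the digitized cervical curve, rigidly
reorient the crown so that plane becomes the xy-plane with the lingual side
parallel to the x-axis (buccal towards +y), project the outline, centre it
on the area centroid, and sample 24 equiangular radial pseudolandmarks
starting from the buccally directed +y ray. Crown diameters (MD, BL) are
the bounding-box extents of the oriented outline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

from .gpa import centroid_size

N_PSEUDOLANDMARKS = 24


class GeometryError(ValueError):
    pass


@dataclass
class PlaneFit:
    point: np.ndarray
    normal: np.ndarray
    rms_residual: float


@dataclass
class OutlinePolygon:
    """Closed, simple crown outline in the oriented frame (buccal = +y)."""

    vertices: np.ndarray
    tooth_side: str = "left"

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise GeometryError("outline needs >= 3 two-dimensional vertices")
        # drop an explicit closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        poly = _ShapelyPolygon(v)
        if not poly.is_valid or not poly.is_simple:
            raise GeometryError("outline polygon is self-intersecting")
        self.vertices = v
        self._poly = poly

    @property
    def shapely(self):
        return self._poly


@dataclass
class PseudolandmarkSet:
    """24 radial pseudolandmarks as unit-centroid-size shape coordinates."""

    points: np.ndarray
    start_index: int = 0
    missing: np.ndarray = None

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.shape != (N_PSEUDOLANDMARKS, 2):
            raise GeometryError(
                f"expected {N_PSEUDOLANDMARKS} x 2 points, got {self.points.shape}"
            )
        if self.missing is None:
            self.missing = np.zeros(N_PSEUDOLANDMARKS, dtype=bool)


@dataclass
class CrownDiameters:
    MD: float
    BL: float


def best_fit_plane(polyline3d):
    """Total-least-squares plane through 3D points (e.g. a cervical curve).

    Minimizes orthogonal distances; the normal is the singular vector of the
    centred points with the smallest singular value.
    """
    pts = np.asarray(polyline3d, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise GeometryError("need >= 3 three-dimensional points")
    centre = pts.mean(axis=0)
    centred = pts - centre
    _, s, Vt = np.linalg.svd(centred, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1e-300):
        raise GeometryError("points are collinear; plane undefined")
    normal = Vt[2]
    rms = float(np.sqrt(np.mean((centred @ normal) ** 2)))
    return PlaneFit(point=centre, normal=normal, rms_residual=rms)


def _rotation_from_to(a, b):
    """Proper rotation matrix taking unit vector a to unit vector b."""
    a = a / np.linalg.norm(a)
    b = b / np.linalg.norm(b)
    v = np.cross(a, b)
    c = float(np.dot(a, b))
    if np.linalg.norm(v) < 1e-15:
        if c > 0:
            return np.eye(3)
        # opposite: rotate 180 deg about any axis orthogonal to a
        axis = np.eye(3)[np.argmin(np.abs(a))]
        axis = axis - a * np.dot(axis, a)
        axis /= np.linalg.norm(axis)
        return 2.0 * np.outer(axis, axis) - np.eye(3)
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def orient_crown(points3d, cervical_plane, lingual_direction):
    """Rigidly move crown points so the cervical plane is the xy-plane and
    the lingual direction is parallel to the x-axis.

    ``lingual_direction`` is digitized metadata: a vector along the lingual
    wall of the crown. The transform is rigid (rotation + translation of the
    plane point to the origin); the returned array preserves shape and size.
    """
    pts = np.asarray(points3d, dtype=float)
    normal = cervical_plane.normal / np.linalg.norm(cervical_plane.normal)
    lingual = np.asarray(lingual_direction, dtype=float)
    in_plane = lingual - normal * np.dot(lingual, normal)
    if np.linalg.norm(in_plane) < 1e-12:
        raise GeometryError("lingual direction parallel to the plane normal")
    R1 = _rotation_from_to(normal, np.array([0.0, 0.0, 1.0]))
    moved = (pts - cervical_plane.point) @ R1.T
    ling2 = R1 @ lingual
    ang = np.arctan2(ling2[1], ling2[0])
    ca, sa = np.cos(-ang), np.sin(-ang)
    R2 = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    return moved @ R2.T


def project_to_plane(points3d):
    """Drop the z coordinate of oriented points (projection onto the
    cervical plane after :func:`orient_crown`)."""
    pts = np.asarray(points3d, dtype=float)
    return pts[:, :2].copy()


def polygon_area_centroid(polygon):
    """Area (not vertex-mean) centroid of a simple closed polygon."""
    if not isinstance(polygon, OutlinePolygon):
        polygon = OutlinePolygon(polygon)
    c = polygon.shapely.centroid
    return np.array([c.x, c.y])


def _ray_crossings(vertices, origin, direction):
    """Parameters t > 0 where origin + t*direction crosses the polygon
    boundary; a crossing within 1e-12 of a vertex is counted once."""
    n = vertices.shape[0]
    ts = []
    for i in range(n):
        p, q = vertices[i], vertices[(i + 1) % n]
        e = q - p
        denom = direction[0] * (-e[1]) - direction[1] * (-e[0])
        if abs(denom) < 1e-15:
            continue
        w = p - origin
        t = (w[0] * (-e[1]) - w[1] * (-e[0])) / denom
        u = (direction[0] * w[1] - direction[1] * w[0]) / denom
        if t > 1e-12 and -1e-12 <= u <= 1.0 - 1e-12:
            ts.append(t)
        elif t > 1e-12 and abs(u - 1.0) <= 1e-12:
            # vertex hit: attribute to this segment's end only
            ts.append(t)
    # merge near-duplicate params (vertex shared by two segments)
    ts.sort()
    merged = []
    for t in ts:
        if not merged or abs(t - merged[-1]) > 1e-9:
            merged.append(t)
    return merged


def radial_pseudolandmarks(polygon, n_points=N_PSEUDOLANDMARKS, clockwise=True):
    """Sample equiangular radial pseudolandmarks from the area centroid.

    Rays start buccally (+y) and sweep in 15-degree steps, clockwise for a
    left tooth in standard occlusal orientation (so the mesial side follows
    the buccal ray). The polygon must be star-shaped about its area
    centroid. The output is centred on the pseudolandmark centroid and
    scaled to unit centroid size (Procrustes shape coordinates).
    """
    if not isinstance(polygon, OutlinePolygon):
        polygon = OutlinePolygon(polygon)
    centroid = polygon_area_centroid(polygon)
    step = 2.0 * np.pi / n_points
    sign = -1.0 if clockwise else 1.0
    raw = np.empty((n_points, 2))
    for j in range(n_points):
        ang = np.pi / 2.0 + sign * step * j  # ray 0 along +y
        direction = np.array([np.cos(ang), np.sin(ang)])
        ts = _ray_crossings(polygon.vertices, centroid, direction)
        if len(ts) != 1:
            raise GeometryError(
                f"polygon not star-shaped about its centroid: ray {j} "
                f"(angle {np.degrees(ang):.1f} deg) crosses the boundary "
                f"{len(ts)} times"
            )
        raw[j] = centroid + ts[0] * direction
    centred = raw - raw.mean(axis=0)
    pts = centred / centroid_size(centred)
    return PseudolandmarkSet(points=pts)


def crown_diameters(outline_or_points):
    """Mesio-distal (x-extent) and bucco-lingual (y-extent) crown diameters
    of an oriented outline, via its axis-aligned bounding box."""
    if isinstance(outline_or_points, OutlinePolygon):
        pts = outline_or_points.vertices
    else:
        pts = np.asarray(outline_or_points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] not in (2, 3):
            raise GeometryError("expected 2D outline or oriented crown points")
        if pts.shape[1] == 3:
            raise GeometryError(
                "orientation required: project oriented points to the "
                "cervical plane first (orient_crown + project_to_plane)"
            )
    md = float(pts[:, 0].max() - pts[:, 0].min())
    bl = float(pts[:, 1].max() - pts[:, 1].min())
    return CrownDiameters(MD=md, BL=bl)
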