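"""Baseline (height, radius) and discrete-curvature features per segment.

Curvature follows the mixed Finite-Element/Finite-Volume discretization of
Meyer et al.: Gaussian curvature is the angle deficit at a vertex divided
by its mixed Voronoi area (with the obtuse-triangle correction), and mean
curvature is half the norm of the cotangent-weighted Laplace vector over
the same area.  Boundary vertices are excluded from every statistic — on
an open disk-like patch their angle deficit is meaningless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .meshes import (DegenerateInputError, Plane, PointSet, TriangleMesh,
                     radius_query, ransac_fit_plane)

#: Starting guess and step of the iterative 90%-containment radius, µm.
RADIUS_START_UM = 100.0
RADIUS_STEP_UM = 10.0
RADIUS_CONTAINMENT = 0.90

CURVATURE_FEATURE_NAMES = [
    "max_gauss", "min_gauss", "max_mean", "min_mean",
    "k_ratio", "k_positive_ratio",
]
BASELINE_FEATURE_NAMES = ["height_um", "radius_um"]


class EmptyFieldError(ValueError):
    """Raised when a mesh has no interior vertices to compute curvature on."""


class UndefinedRatioError(ValueError):
    """Raised when both curvature-sign counts are zero."""


@dataclass
class CurvatureField:
    """Per-vertex discrete curvatures of a patch.

    gaussian: µm^-2; mean: µm^-1; angle_sum: incident-angle sums (rad);
    mixed_area: µm^2; boundary: mask of boundary vertices (excluded from
    statistics); angle_deficit: raw 2*pi - angle_sum debug channel.
    """

    gaussian: np.ndarray
    mean: np.ndarray
    angle_sum: np.ndarray
    mixed_area: np.ndarray
    boundary: np.ndarray

    @property
    def angle_deficit(self) -> np.ndarray:
        return 2.0 * np.pi - self.angle_sum

    def interior(self, channel: np.ndarray) -> np.ndarray:
        return channel[~self.boundary]


def _face_angles(v: np.ndarray, t: np.ndarray) -> np.ndarray:
    """(m, 3) interior angles, column j = angle at vertex t[:, j]."""
    p0, p1, p2 = v[t[:, 0]], v[t[:, 1]], v[t[:, 2]]
    angles = np.empty((len(t), 3))
    for j, (a, b, c) in enumerate(((p0, p1, p2), (p1, p2, p0), (p2, p0, p1))):
        u, w = b - a, c - a
        cosang = np.einsum("ij,ij->i", u, w) / (
            np.linalg.norm(u, axis=1) * np.linalg.norm(w, axis=1))
        angles[:, j] = np.arccos(np.clip(cosang, -1.0, 1.0))
    return angles


def discrete_curvatures(patch: TriangleMesh) -> CurvatureField:
    """Meyer-style Gaussian and mean curvature at every vertex.

    Mixed area: per non-obtuse triangle the Voronoi split
    (|e1|^2 cot a1 + |e2|^2 cot a2)/8; per obtuse triangle area/2 at the
    obtuse vertex and area/4 at the other two.
    """
    v, t = patch.vertices, patch.triangles
    if not len(t):
        raise EmptyFieldError("patch has no triangles")
    boundary = patch.boundary_vertex_mask()
    if boundary.all():
        raise EmptyFieldError("patch has no interior vertices")
    n = patch.n_vertices
    ang = _face_angles(v, t)
    cot = 1.0 / np.tan(np.clip(ang, 1e-12, np.pi - 1e-12))

    p = v[t]                                   # (m, 3, 3)
    e_sq = np.empty((len(t), 3))               # opposite-edge squared length
    e_sq[:, 0] = np.sum((p[:, 1] - p[:, 2]) ** 2, axis=1)
    e_sq[:, 1] = np.sum((p[:, 2] - p[:, 0]) ** 2, axis=1)
    e_sq[:, 2] = np.sum((p[:, 0] - p[:, 1]) ** 2, axis=1)
    tri_area = 0.5 * np.linalg.norm(
        np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1)

    obtuse = ang > np.pi / 2                   # (m, 3)
    any_obtuse = obtuse.any(axis=1)

    a_mixed = np.zeros(n)
    angle_sum = np.zeros(n)
    lap = np.zeros((n, 3))                     # cotangent Laplace accumulator
    for j in range(3):
        jn, jp = (j + 1) % 3, (j + 2) % 3
        vi = t[:, j]
        # Voronoi-safe area at corner j: (|e_jn|^2 cot(ang_jn) + |e_jp|^2 cot(ang_jp))/8
        voronoi = (e_sq[:, jn] * cot[:, jn] + e_sq[:, jp] * cot[:, jp]) / 8.0
        contrib = np.where(
            any_obtuse,
            np.where(obtuse[:, j], tri_area / 2.0, tri_area / 4.0),
            voronoi)
        np.add.at(a_mixed, vi, contrib)
        np.add.at(angle_sum, vi, ang[:, j])
        # Laplace: cot of the angles opposite edge (vi, v_other)
        for other, opp in ((jn, jp), (jp, jn)):
            w = cot[:, opp][:, None] * (v[t[:, other]] - v[vi])
            np.add.at(lap, vi, w)

    with np.errstate(divide="ignore", invalid="ignore"):
        gaussian = (2.0 * np.pi - angle_sum) / a_mixed
        mean = 0.5 * np.linalg.norm(lap / (2.0 * a_mixed[:, None]), axis=1)
    gaussian[a_mixed <= 0] = 0.0
    mean[a_mixed <= 0] = 0.0
    return CurvatureField(gaussian, mean, angle_sum, a_mixed, boundary)


@dataclass
class GeometricFeatures:
    height_um: float = np.nan
    radius_um: float = np.nan
    max_gauss: float = np.nan
    min_gauss: float = np.nan
    max_mean: float = np.nan
    min_mean: float = np.nan
    k_ratio: float = np.nan
    k_positive_ratio: float = np.nan
    n_positive: int = 0
    n_negative: int = 0

    def as_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in BASELINE_FEATURE_NAMES + CURVATURE_FEATURE_NAMES}


def curvature_summary(field: CurvatureField) -> GeometricFeatures:
    """Aggregate a curvature field into the per-segment curvature features.

    x = #(interior vertices with K > 0), y = #(K < 0); K = 0 counts in
    neither.  k_ratio = min(x, y)/max(x, y); k_positive_ratio = x/(x + y).
    """
    k = field.interior(field.gaussian)
    h = field.interior(field.mean)
    if len(k) == 0:
        raise EmptyFieldError("no interior vertices")
    x = int(np.sum(k > 0))
    y = int(np.sum(k < 0))
    if x + y == 0:
        raise UndefinedRatioError("no vertices with nonzero curvature sign")
    k_ratio = (y / x) if y <= x else (x / y)
    return GeometricFeatures(
        max_gauss=float(k.max()), min_gauss=float(k.min()),
        max_mean=float(h.max()), min_mean=float(h.min()),
        k_ratio=float(k_ratio), k_positive_ratio=x / (x + y),
        n_positive=x, n_negative=y)


def compute_radius(points: PointSet, m_point) -> float:
    """90%-containment radius of the segment around M, found iteratively:
    start at 100 µm and grow in 10 µm steps until the closed ball holds at
    least 90% of the points; return the stopping radius."""
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float)
    if len(pts) == 0:
        raise DegenerateInputError("radius needs at least one point")
    d = np.linalg.norm(pts - np.asarray(m_point, float), axis=1)
    need = RADIUS_CONTAINMENT * len(pts)
    i = RADIUS_START_UM
    while np.sum(d <= i) < need:
        i += RADIUS_STEP_UM
    return float(i)


def compute_height(patch: TriangleMesh | PointSet, m_point, r_seg: float,
                   inlier_threshold: float | None = None,
                   n_iterations: int | None = None,
                   rng: np.random.Generator | int | None = 0) -> float:
    """Papilla height: cut the radius-``r_seg`` region around M, fit its
    base plane by RANSAC, return the unsigned distance from the plane to M."""
    if isinstance(patch, TriangleMesh):
        pts = PointSet(patch.vertices)
    else:
        pts = patch
    m_point = np.asarray(m_point, dtype=np.float64)
    region = radius_query(pts, m_point, r_seg)
    if len(region) < 3:
        raise DegenerateInputError("height region has fewer than 3 points")
    kwargs = {}
    if inlier_threshold is not None:
        kwargs["inlier_threshold"] = inlier_threshold
    if n_iterations is not None:
        kwargs["n_iterations"] = n_iterations
    plane = ransac_fit_plane(region, rng=rng, **kwargs)
    return float(plane.distance(m_point)[0])


def geometric_feature_vector(patch: TriangleMesh, m_point, *,
                             radius_from: PointSet | None = None,
                             inlier_threshold: float | None = None,
                             rng: np.random.Generator | int | None = 0
                             ) -> GeometricFeatures:
    """Baseline + curvature features of one segment patch.

    ``radius_from`` overrides the point set used for the containment radius
    (defaults to the patch vertices)."""
    pts = radius_from if radius_from is not None else PointSet(patch.vertices)
    r_seg = compute_radius(pts, m_point)
    h = compute_height(patch, m_point, r_seg,
                       inlier_threshold=inlier_threshold, rng=rng)
    feats = curvature_summary(discrete_curvatures(patch))
    feats.height_um = h
    feats.radius_um = r_seg
    return feats
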