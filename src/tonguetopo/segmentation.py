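"""Candidate papilla segment extraction.

A segment is cut around a local maximum: pick a seed point P, take the
points within r + delta of P, keep the edge-connected component containing
P, fit its base plane by RANSAC, locate the component point M furthest
above the plane, and cut the radius-r patch around M.  The whole-surface
sweep repeats this from random unvisited seeds, ignoring any new maximum
that falls inside a previously accepted segment.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .meshes import (DegenerateInputError, Plane, PointSet, TriangleMesh,
                     ransac_fit_plane)
from .synthesis import AnnotatedSurface, rng_stream

log = logging.getLogger("tonguetopo")

# r = max(r_fungiform, r_filiform); radii that work well for automated
# detection of both papilla types, µm.
R_FUNGIFORM_UM = 439.0
R_FILIFORM_UM = 177.5
DEFAULT_CUT_RADIUS_UM = max(R_FUNGIFORM_UM, R_FILIFORM_UM)
DEFAULT_DELTA_UM = 100.0
#: consecutive fruitless seed draws before a sweep stops
DEFAULT_MAX_CONSECUTIVE_FAILURES = 60


@dataclass
class Segment:
    """A disk-like candidate patch cut around a local maximum M."""

    patch: TriangleMesh
    seed_point: np.ndarray          # P, 3D µm
    base_plane: Plane
    m_point: np.ndarray             # M, 3D µm
    m_index: int                    # vertex index of M in the parent mesh
    cut_radius: float
    delta: float
    label: str = "unlabelled"       # fungiform | filiform | none | unlabelled
    metadata: dict = field(default_factory=dict)

    @property
    def height_above_plane(self) -> float:
        return float(self.base_plane.signed_distance(self.m_point)[0])

    def points(self) -> PointSet:
        return PointSet(self.patch.vertices)


class _MeshIndex:
    """Per-mesh acceleration state shared across many extractions."""

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        self.tree = cKDTree(mesh.vertices)
        adj = mesh.adjacency()
        self.indptr, self.indices = adj.indptr, adj.indices
        # area-weighted outward vertex normals (consistent winding assumed)
        t, v = mesh.triangles, mesh.vertices
        fn = np.cross(v[t[:, 1]] - v[t[:, 0]], v[t[:, 2]] - v[t[:, 0]])
        vn = np.zeros_like(v)
        for j in range(3):
            np.add.at(vn, t[:, j], fn)
        nrm = np.linalg.norm(vn, axis=1, keepdims=True)
        nrm[nrm == 0] = 1.0
        self.vertex_normals = vn / nrm

    def ball(self, center, radius: float) -> np.ndarray:
        idx = np.asarray(sorted(self.tree.query_ball_point(center, radius)),
                         dtype=np.int64)
        if len(idx):
            d = np.linalg.norm(self.mesh.vertices[idx] - center, axis=1)
            idx = idx[d <= radius]
        return idx

    def component(self, subset: np.ndarray, seed: int) -> np.ndarray:
        """BFS over mesh edges restricted to ``subset``."""
        in_sub = np.zeros(len(self.mesh.vertices), dtype=bool)
        in_sub[subset] = True
        seen = np.zeros_like(in_sub)
        seen[seed] = True
        queue = deque([seed])
        out = [seed]
        while queue:
            u = queue.popleft()
            for w in self.indices[self.indptr[u]:self.indptr[u + 1]]:
                if in_sub[w] and not seen[w]:
                    seen[w] = True
                    out.append(int(w))
                    queue.append(int(w))
        return np.sort(np.asarray(out, dtype=np.int64))


def extract_segment(mesh: TriangleMesh, seed_vertex: int,
                    r: float = DEFAULT_CUT_RADIUS_UM,
                    delta: float = DEFAULT_DELTA_UM,
                    inlier_threshold: float | None = None,
                    n_iterations: int | None = None,
                    rng: np.random.Generator | int | None = 0,
                    _index: _MeshIndex | None = None) -> Segment:
    """Cut one candidate segment around seed vertex P.

    Steps: (1) B = vertices within r + delta of P; (2) restrict to the
    edge-connected component containing P; (3) RANSAC base plane of the
    component, oriented along the component's mean outward normal; (4) M =
    component vertex with maximum signed height above the plane; (5) patch
    = M's connected component of the vertices within r of M.
    """
    if r <= 0 or delta <= 0:
        raise ValueError("r and delta must be positive")
    index = _index or _MeshIndex(mesh)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    p_point = mesh.vertices[seed_vertex]

    ball = index.ball(p_point, r + delta)
    comp = index.component(ball, seed_vertex)
    if len(comp) < 3:
        raise DegenerateInputError("connected candidate set has < 3 points")

    kwargs = {}
    if inlier_threshold is not None:
        kwargs["inlier_threshold"] = inlier_threshold
    if n_iterations is not None:
        kwargs["n_iterations"] = n_iterations
    plane = ransac_fit_plane(PointSet(mesh.vertices[comp]), rng=rng, **kwargs)
    mean_normal = index.vertex_normals[comp].mean(axis=0)
    if plane.normal @ mean_normal < 0:
        plane = plane.flipped()

    heights = plane.signed_distance(mesh.vertices[comp])
    m_local = int(np.argmax(heights))           # ties -> lowest index
    m_index = int(comp[m_local])
    m_point = mesh.vertices[m_index]

    in_r = index.ball(m_point, r)
    in_r = np.intersect1d(in_r, comp, assume_unique=False)
    patch_idx = index.component(in_r, m_index)
    patch = mesh.submesh(patch_idx)
    return Segment(patch=patch, seed_point=p_point.copy(), base_plane=plane,
                   m_point=m_point.copy(), m_index=m_index,
                   cut_radius=r, delta=delta)


def sweep_surface(mesh: TriangleMesh,
                  r: float = DEFAULT_CUT_RADIUS_UM,
                  delta: float = DEFAULT_DELTA_UM,
                  max_iterations: int | None = None,
                  seed: int = 0,
                  max_consecutive_failures: int = DEFAULT_MAX_CONSECUTIVE_FAILURES,
                  suppression_radius: float | None = None,
                  inlier_threshold: float | None = None,
                  n_iterations: int | None = None) -> list[Segment]:
    """Sweep a surface, extracting candidate segments from random unvisited
    seeds with duplicate suppression.

    A new segment is accepted only if its M lies at least
    ``suppression_radius`` (default: r) from every previously accepted M;
    vertices inside accepted segments are removed from the seed pool.  The
    sweep ends when the pool is empty, ``max_iterations`` seeds have been
    drawn, or ``max_consecutive_failures`` draws in a row produced nothing
    new.  Deterministic given ``seed``.
    """
    index = _MeshIndex(mesh)
    rng = rng_stream(seed, "sweep")
    supp = r if suppression_radius is None else suppression_radius
    n = mesh.n_vertices

    # phase 1: harvest candidate maxima from random seeds until the surface
    # is covered (every vertex visited or inside some candidate's r-ball)
    available = np.ones(n, dtype=bool)
    candidates: list[Segment] = []
    failures = 0
    iterations = 0
    while available.any():
        if max_iterations is not None and iterations >= max_iterations:
            break
        if failures >= max_consecutive_failures:
            break
        pool = np.flatnonzero(available)
        seed_vertex = int(rng.choice(pool))
        available[seed_vertex] = False
        iterations += 1
        try:
            seg = extract_segment(mesh, seed_vertex, r, delta,
                                  inlier_threshold=inlier_threshold,
                                  n_iterations=n_iterations,
                                  rng=rng, _index=index)
            # refine to a fixed point: re-cut centred on M so the patch is a
            # full ball around the maximum (a far-away seed only sees a
            # papilla's flank at the edge of its candidate set)
            for _ in range(4):
                if seg.m_index == seed_vertex:
                    break
                seed_vertex = seg.m_index
                seg = extract_segment(mesh, seed_vertex, r, delta,
                                      inlier_threshold=inlier_threshold,
                                      n_iterations=n_iterations,
                                      rng=rng, _index=index)
        except DegenerateInputError as exc:
            log.warning("sweep: degenerate seed %d skipped (%s)", seed_vertex, exc)
            failures += 1
            continue
        if candidates and min(
                float(np.linalg.norm(c.m_point - seg.m_point))
                for c in candidates) < 1e-9:
            failures += 1          # same maximum found again
            # the seed's whole exploration ball keeps pointing at the same
            # maximum; retire it so coverage progresses
            available[index.ball(seg.seed_point, r)] = False
        else:
            candidates.append(seg)
            failures = 0
        available[index.ball(seg.m_point, supp)] = False
        available[index.ball(seg.seed_point, delta)] = False

    # phase 2: greedy acceptance by decreasing prominence (height above the
    # segment's base plane), each accepted maximum suppressing later
    # candidates within the suppression radius.  Prominence ordering keeps
    # papilla peaks from being shadowed by earlier flat-region maxima.
    order = sorted(range(len(candidates)),
                   key=lambda i: (-candidates[i].height_above_plane, i))
    accepted: list[Segment] = []
    accepted_m: list[np.ndarray] = []
    for i in order:
        seg = candidates[i]
        if accepted_m and np.min(np.linalg.norm(
                np.asarray(accepted_m) - seg.m_point, axis=1)) < supp:
            continue
        accepted.append(seg)
        accepted_m.append(seg.m_point)
    return accepted


# ---------------------------------------------------------------------------
# Ground-truth labelling helpers for synthetic surfaces
# ---------------------------------------------------------------------------

def label_segments(segments: list[Segment], surface: AnnotatedSurface,
                   match_tol: float = 50.0) -> list[Segment]:
    """Label swept segments against planted annotations: a segment whose M
    is within ``match_tol`` µm of a planted apex takes that papilla's type;
    within the papilla's base disk it stays unlabelled (partial overlap);
    otherwise it is 'none'."""
    apexes = surface.apex_points
    for seg in segments:
        if len(apexes) == 0:
            seg.label = "none"
            continue
        d = np.linalg.norm(apexes - seg.m_point, axis=1)
        i = int(np.argmin(d))
        if d[i] <= match_tol:
            seg.label = surface.papillae[i].type
        elif d[i] <= surface.papillae[i].base_radius:
            seg.label = "unlabelled"
        else:
            seg.label = "none"
        seg.metadata.update(participant=surface.participant.participant_id,
                            gender=surface.participant.gender,
                            age=surface.participant.age,
                            age_group=surface.participant.age_group)
    return segments


def annotated_segments(surface: AnnotatedSurface,
                       n_none: int = 0,
                       r: float = DEFAULT_CUT_RADIUS_UM,
                       delta: float = DEFAULT_DELTA_UM,
                       seed: int = 0,
                       inlier_threshold: float | None = None,
                       n_iterations: int | None = None) -> list[Segment]:
    """Extract one labelled segment per planted papilla (seeded near its
    apex) plus ``n_none`` segments at papilla-free locations.

    The synthetic stand-in for the study's manually labelled segment set:
    labels come from the generator's ground truth instead of an annotator.
    """
    index = _MeshIndex(surface.mesh)
    rng = rng_stream(seed, "annotated_segments")
    segments: list[Segment] = []
    centers2d = np.asarray([p.center for p in surface.papillae]) \
        if surface.papillae else np.empty((0, 2))
    for spec, apex in zip(surface.papillae, surface.apex_points):
        _, seed_vertex = index.tree.query(apex)
        seg = extract_segment(surface.mesh, int(seed_vertex), r, delta,
                              inlier_threshold=inlier_threshold,
                              n_iterations=n_iterations, rng=rng, _index=index)
        seg.label = spec.type
        segments.append(seg)

    # none segments: seeds whose r+delta ball is clear of every papilla disk
    verts2d = surface.mesh.vertices[:, :2]
    if n_none > 0:
        clear = np.ones(len(verts2d), dtype=bool)
        if len(centers2d):
            # keep every papilla apex out of the seed's r+delta ball; outer
            # flanks of farther papillae may still graze the segment, which
            # mirrors how real non-papillated patches look
            for spec in surface.papillae:
                d2 = np.linalg.norm(verts2d - spec.center, axis=1)
                clear &= d2 > (r + delta)
        # stay away from the sheet border so the component is disk-like
        lo, hi = verts2d.min(0), verts2d.max(0)
        inside = np.all((verts2d > lo + 0.4 * r) & (verts2d < hi - 0.4 * r), axis=1)
        pool = np.flatnonzero(clear & inside)
        if len(pool) == 0:
            raise DegenerateInputError(
                "no papilla-free region large enough for a 'none' segment")
        picks = rng.choice(pool, size=min(n_none, len(pool)), replace=False)
        for seed_vertex in np.atleast_1d(picks):
            seg = extract_segment(surface.mesh, int(seed_vertex), r, delta,
                                  inlier_threshold=inlier_threshold,
                                  n_iterations=n_iterations, rng=rng, _index=index)
            seg.label = "none"
            segments.append(seg)

    for seg in segments:
        seg.metadata.update(participant=surface.participant.participant_id,
                            gender=surface.participant.gender,
                            age=surface.participant.age,
                            age_group=surface.participant.age_group)
    return segments
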