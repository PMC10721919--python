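"""Triangle-mesh data model, I/O and spatial queries.

All coordinates throughout the pipeline are micrometres (µm).  The mesh is
the reconstructed tongue surface on which segments are cut; the spatial
queries here (closed-ball radius search, edge connectivity, RANSAC plane
fits) are the primitives the segmentation and feature stages build on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import trimesh
from scipy import sparse
from scipy.sparse.csgraph import breadth_first_order
from scipy.spatial import cKDTree

log = logging.getLogger("tonguetopo")

#: Default point-to-plane inlier threshold for RANSAC base-plane fits, µm.
#: Kept well below papilla heights so a papilla never dominates the base.
RANSAC_INLIER_THRESHOLD_UM = 20.0
#: Default number of random 3-point plane hypotheses per RANSAC fit.
RANSAC_N_ITERATIONS = 1000


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be parsed or violates mesh invariants."""


class DegenerateInputError(ValueError):
    """Raised when a geometric operation receives degenerate input."""


@dataclass
class TriangleMesh:
    """A triangulated surface: ``vertices`` (n, 3) float64 µm, ``triangles``
    (m, 3) int 0-based vertex indices.  Optional per-vertex scalar channels
    (e.g. curvature) live in ``vertex_attributes``."""

    vertices: np.ndarray
    triangles: np.ndarray
    vertex_attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.vertices = np.ascontiguousarray(self.vertices, dtype=np.float64)
        self.triangles = np.ascontiguousarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshFormatError("vertices must be an (n, 3) array")
        if self.triangles.size and (
            self.triangles.ndim != 2 or self.triangles.shape[1] != 3
        ):
            raise MeshFormatError("triangles must be an (m, 3) array")
        if self.triangles.size == 0:
            self.triangles = self.triangles.reshape(0, 3)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        n = len(self.vertices)
        if self.triangles.size:
            if self.triangles.min() < 0 or self.triangles.max() >= n:
                raise MeshFormatError(
                    f"triangle index out of range (n_vertices={n})"
                )
            t = self.triangles
            if np.any((t[:, 0] == t[:, 1]) | (t[:, 1] == t[:, 2]) | (t[:, 0] == t[:, 2])):
                raise MeshFormatError("triangle repeats a vertex")
            key = np.sort(t, axis=1)
            if len(np.unique(key, axis=0)) != len(key):
                raise MeshFormatError("duplicate triangles")

    # -- derived structure --------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    def edges(self) -> np.ndarray:
        """Unique undirected edges as a sorted (k, 2) index array."""
        if not self.triangles.size:
            return np.empty((0, 2), dtype=np.int64)
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e.sort(axis=1)
        return np.unique(e, axis=0)

    def adjacency(self) -> sparse.csr_matrix:
        """Vertex adjacency over mesh edges (symmetric boolean CSR)."""
        e = self.edges()
        n = self.n_vertices
        if not len(e):
            return sparse.csr_matrix((n, n), dtype=bool)
        data = np.ones(len(e), dtype=bool)
        a = sparse.coo_matrix((data, (e[:, 0], e[:, 1])), shape=(n, n))
        return (a + a.T).tocsr()

    def boundary_vertex_mask(self) -> np.ndarray:
        """True for vertices on an open boundary (edge with one incident face)."""
        mask = np.zeros(self.n_vertices, dtype=bool)
        if not self.triangles.size:
            return mask
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e.sort(axis=1)
        uniq, counts = np.unique(e, axis=0, return_counts=True)
        b = uniq[counts == 1]
        mask[np.unique(b)] = True
        return mask

    def submesh(self, vertex_indices: np.ndarray) -> "TriangleMesh":
        """Induced submesh on ``vertex_indices`` (triangles with all three
        vertices in the subset); vertex order follows ``vertex_indices``."""
        vertex_indices = np.asarray(vertex_indices, dtype=np.int64)
        remap = np.full(self.n_vertices, -1, dtype=np.int64)
        remap[vertex_indices] = np.arange(len(vertex_indices))
        if self.triangles.size:
            keep = np.all(remap[self.triangles] >= 0, axis=1)
            tri = remap[self.triangles[keep]]
        else:
            tri = np.empty((0, 3), dtype=np.int64)
        return TriangleMesh(self.vertices[vertex_indices], tri)


@dataclass
class PointSet:
    """A bag of 3D points (µm) with optional provenance (source mesh vertex
    indices, or None for free points).  All distances are ambient Euclidean."""

    points: np.ndarray
    provenance: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ValueError("points must be an (n, 3) array")
        if self.provenance is not None:
            self.provenance = np.asarray(self.provenance, dtype=np.int64)

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class Plane:
    """Plane {x : n·x + d = 0} with unit normal ``normal`` and offset ``d``;
    carries the inlier threshold and count from the fit that produced it."""

    normal: np.ndarray
    offset: float
    inlier_threshold: float = np.nan
    inlier_count: int = 0

    def __post_init__(self) -> None:
        self.normal = np.asarray(self.normal, dtype=np.float64)
        nrm = np.linalg.norm(self.normal)
        if abs(nrm - 1.0) > 1e-9:
            self.normal = self.normal / nrm

    def signed_distance(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        return points @ self.normal + self.offset

    def distance(self, points: np.ndarray) -> np.ndarray:
        return np.abs(self.signed_distance(points))

    def flipped(self) -> "Plane":
        return Plane(-self.normal, -self.offset, self.inlier_threshold,
                     self.inlier_count)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

_FORMATS = {"ply", "obj"}


def read_mesh(path, fmt: str | None = None) -> TriangleMesh:
    """Read a PLY or OBJ mesh. Vertex order is preserved; faces become
    0-based indices regardless of format."""
    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt}")
    try:
        tm = trimesh.load(str(path), file_type=fmt, process=False,
                          maintain_order=True)
    except Exception as exc:  # noqa: BLE001 - normalise parser errors
        raise MeshFormatError(f"cannot parse {path}: {exc}") from exc
    if isinstance(tm, trimesh.Scene):
        geoms = list(tm.geometry.values())
        if not geoms:
            raise MeshFormatError(f"{path}: empty scene")
        tm = geoms[0]
    verts = np.asarray(tm.vertices, dtype=np.float64)
    faces = (np.asarray(tm.faces, dtype=np.int64)
             if getattr(tm, "faces", None) is not None and len(tm.faces)
             else np.empty((0, 3), np.int64))
    if len(verts) == 0:
        raise MeshFormatError(f"{path}: empty vertex set")
    mesh = TriangleMesh(verts, faces)
    bb = mesh.vertices.min(0), mesh.vertices.max(0)
    log.info("read %s: V=%d F=%d bbox=%s..%s", path, mesh.n_vertices,
             len(mesh.triangles), bb[0], bb[1])
    return mesh


def write_mesh(mesh: TriangleMesh, path, fmt: str | None = None) -> None:
    """Write a mesh as ASCII PLY or OBJ (round-trips through :func:`read_mesh`)."""
    fmt = (fmt or str(path).rsplit(".", 1)[-1]).lower()
    if fmt not in _FORMATS:
        raise MeshFormatError(f"unsupported mesh format: {fmt}")
    mesh.validate()
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    try:
        if fmt == "ply":
            # ASCII PLY with double-precision vertices (library exporters
            # quantize to float32, which loses µm-scale precision)
            with open(path, "w") as fh:
                fh.write("ply\nformat ascii 1.0\n")
                fh.write(f"element vertex {mesh.n_vertices}\n")
                fh.write("property double x\nproperty double y\nproperty double z\n")
                fh.write(f"element face {len(mesh.triangles)}\n")
                fh.write("property list uchar int vertex_indices\nend_header\n")
                for x, y, z in mesh.vertices:
                    fh.write(f"{x:.17g} {y:.17g} {z:.17g}\n")
                for a, b, c in mesh.triangles:
                    fh.write(f"3 {a} {b} {c}\n")
        else:
            tm.export(str(path), file_type="obj")
    except OSError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise OSError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Spatial queries
# ---------------------------------------------------------------------------

def radius_query(points: PointSet, center, radius: float) -> PointSet:
    """All points within the *closed* Euclidean ball of ``radius`` µm around
    ``center``.  A KD-tree accelerates the query; the result is exactly the
    set an exhaustive distance scan would return."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    center = np.asarray(center, dtype=np.float64)
    if len(points) == 0:
        return PointSet(np.empty((0, 3)), np.empty(0, dtype=np.int64))
    tree = cKDTree(points.points)
    idx = tree.query_ball_point(center, radius)
    # query_ball_point uses <=; re-check to make the closed-ball contract
    # independent of the acceleration structure's tolerance handling.
    idx = np.asarray(sorted(idx), dtype=np.int64)
    if len(idx):
        d = np.linalg.norm(points.points[idx] - center, axis=1)
        idx = idx[d <= radius]
    prov = points.provenance[idx] if points.provenance is not None else idx
    return PointSet(points.points[idx], prov)


def connected_component_of(mesh: TriangleMesh, vertex_subset, seed: int) -> np.ndarray:
    """Vertices of ``vertex_subset`` reachable from ``seed`` along mesh edges
    with both endpoints inside the subset.  Returns sorted indices into the
    original mesh."""
    vertex_subset = np.asarray(vertex_subset, dtype=np.int64)
    if seed not in set(vertex_subset.tolist()):
        raise ValueError("seed vertex must be a member of vertex_subset")
    in_sub = np.zeros(mesh.n_vertices, dtype=bool)
    in_sub[vertex_subset] = True
    adj = mesh.adjacency()
    # restrict adjacency to the subset
    mask_diag = sparse.diags(in_sub.astype(np.int8), dtype=np.int8)
    sub_adj = mask_diag @ adj.astype(np.int8) @ mask_diag
    order = breadth_first_order(sub_adj, seed, directed=False,
                                return_predecessors=False)
    reach = np.asarray(order, dtype=np.int64)
    reach = reach[in_sub[reach]]
    return np.sort(reach)


def ransac_fit_plane(points: PointSet, inlier_threshold: float = RANSAC_INLIER_THRESHOLD_UM,
                     n_iterations: int = RANSAC_N_ITERATIONS,
                     rng: np.random.Generator | int | None = 0) -> Plane:
    """RANSAC plane fit: ``n_iterations`` random 3-point hypotheses, keep the
    one with most inliers (|signed distance| <= threshold), then least-squares
    refit (SVD) on that inlier set.  Deterministic given the RNG seed."""
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, dtype=np.float64)
    n = len(pts)
    if n < 3:
        raise DegenerateInputError("plane fit needs at least 3 points")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # check collinearity once
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise DegenerateInputError("all points are collinear")

    trips = rng.integers(0, n, size=(n_iterations, 3))
    p0, p1, p2 = pts[trips[:, 0]], pts[trips[:, 1]], pts[trips[:, 2]]
    normals = np.cross(p1 - p0, p2 - p0)
    norms = np.linalg.norm(normals, axis=1)
    ok = norms > 1e-12
    best_count, best_i = -1, -1
    # chunked inlier counting keeps memory bounded for large patches
    idx_ok = np.flatnonzero(ok)
    for start in range(0, len(idx_ok), 256):
        sel = idx_ok[start:start + 256]
        nrm = normals[sel] / norms[sel][:, None]
        d = np.abs((pts[None, :, :] - p0[sel][:, None, :]) @ nrm[:, :, None]).squeeze(-1)
        counts = (d <= inlier_threshold).sum(axis=1)
        j = int(np.argmax(counts))
        if counts[j] > best_count:
            best_count = int(counts[j])
            best_i = int(sel[j])
    if best_i < 0:
        raise DegenerateInputError("no valid plane hypothesis found")
    nrm = normals[best_i] / norms[best_i]
    d0 = -nrm @ pts[trips[best_i, 0]]
    dist = np.abs(pts @ nrm + d0)
    inliers = pts[dist <= inlier_threshold]
    # least-squares refit on the final inlier set
    c = inliers.mean(axis=0)
    _, _, vh = np.linalg.svd(inliers - c, full_matrices=False)
    normal = vh[-1]
    if normal @ nrm < 0:
        normal = -normal
    offset = -float(normal @ c)
    final_count = int((np.abs(pts @ normal + offset) <= inlier_threshold).sum())
    return Plane(normal, offset, inlier_threshold, final_count)
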