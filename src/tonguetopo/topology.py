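"""Vietoris–Rips persistent homology of segment point clouds and the
twelve one-number diagram summaries used as topological features.

The filtration convention: an edge enters the complex at its Euclidean
length, a triangle at its diameter (longest edge).  Dimension-0 classes are
all born at 0; their finite death times equal the single-linkage merge
heights, i.e. the minimum-spanning-tree edge lengths.  Dimension-1 classes
are computed by column reduction of the triangle boundary matrix over F2
(numba-accelerated).  The filtration is truncated at the *enclosing radius*
R = min_i max_j d(i, j): at any scale t >= R the complex is a cone and hence
H1-trivial, so the H0/H1 diagram is identical to the complete filtration's
while the triangle count drops sharply.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from numba.typed import List as NumbaList
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial.distance import pdist, squareform

from .meshes import DegenerateInputError, PointSet

#: Number of points each segment cloud is subsampled to before persistence.
DEFAULT_SUBSAMPLE = 1000
#: "Short bar" length window (0, hi] in µm.
SHORT_BAR_HI_UM = 10.0
#: Persistence-landscape sampling grid for the L2 amplitude.
LANDSCAPE_GRID = 1000
#: Persistence-image raster resolution and relative Gaussian bandwidth.
IMAGE_RESOLUTION = 100
IMAGE_BANDWIDTH_FRACTION = 0.1

TOPO_FEATURE_NAMES = [
    "short_bars_h0", "short_bars_h1",
    "persistent_entropy_h0", "persistent_entropy_h1",
    "amp_landscape_h0", "amp_landscape_h1",
    "amp_image_h0", "amp_image_h1",
    "amp_wasserstein_h0", "amp_wasserstein_h1",
    "amp_bottleneck_h0", "amp_bottleneck_h1",
]


class UndefinedFeatureError(ValueError):
    """Raised when a diagram summary is undefined for the given diagram."""


@dataclass
class PersistenceDiagram:
    """Finite intervals per homology dimension, filtration units µm.

    ``intervals[q]`` is an (n_q, 2) array of (birth, death) with death >=
    birth; essential (infinite-death) classes are stored separately in
    ``essential[q]`` as birth values.
    """

    intervals: dict = field(default_factory=dict)
    essential: dict = field(default_factory=dict)

    def dim(self, q: int) -> np.ndarray:
        arr = self.intervals.get(q)
        if arr is None or len(arr) == 0:
            return np.empty((0, 2))
        return np.asarray(arr, dtype=np.float64)

    def lifetimes(self, q: int) -> np.ndarray:
        d = self.dim(q)
        return d[:, 1] - d[:, 0]


# ---------------------------------------------------------------------------
# Subsampling
# ---------------------------------------------------------------------------

def subsample_points(points: PointSet, n: int = DEFAULT_SUBSAMPLE,
                     rng: np.random.Generator | int | None = 0) -> PointSet:
    """Uniform sample without replacement of min(n, len) points."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    m = len(points)
    if m <= n:
        return PointSet(points.points.copy(),
                        None if points.provenance is None else points.provenance.copy())
    idx = np.sort(rng.choice(m, size=n, replace=False))
    prov = points.provenance[idx] if points.provenance is not None else None
    return PointSet(points.points[idx], prov)


# ---------------------------------------------------------------------------
# Rips persistence
# ---------------------------------------------------------------------------

@njit(cache=True)
def _reduce_triangle_columns(tri_edges, n_edges):
    """F2 column reduction of the triangle boundary matrix.

    tri_edges: (T, 3) int64, per triangle the *edge ranks* of its three
    boundary edges, rows already in filtration order.  Edge rank = position
    of the edge in the filtration (ascending length).  Returns an array of
    (pivot edge rank, triangle row) pairs.
    """
    pivot_owner = np.full(n_edges, -1, dtype=np.int64)
    stored = NumbaList()
    # seed typed list with a dummy so the element type is known
    stored.append(np.empty(0, dtype=np.int64))
    pairs = np.empty((tri_edges.shape[0], 2), dtype=np.int64)
    n_pairs = 0
    cur = np.empty(n_edges, dtype=np.int64)
    tmp = np.empty(n_edges, dtype=np.int64)
    for t in range(tri_edges.shape[0]):
        a, b, c = tri_edges[t, 0], tri_edges[t, 1], tri_edges[t, 2]
        # sort three edge ranks descending
        if a < b:
            a, b = b, a
        if b < c:
            b, c = c, b
        if a < b:
            a, b = b, a
        cur[0], cur[1], cur[2] = a, b, c
        cur_len = 3
        while cur_len > 0:
            piv = cur[0]
            owner = pivot_owner[piv]
            if owner == -1:
                col = np.empty(cur_len, dtype=np.int64)
                col[:] = cur[:cur_len]
                stored.append(col)
                pivot_owner[piv] = len(stored) - 1
                pairs[n_pairs, 0] = piv
                pairs[n_pairs, 1] = t
                n_pairs += 1
                break
            other = stored[owner]
            # symmetric difference of two descending-sorted index lists
            i = 0
            j = 0
            k = 0
            while i < cur_len and j < len(other):
                x = cur[i]
                y = other[j]
                if x == y:
                    i += 1
                    j += 1
                elif x > y:
                    tmp[k] = x
                    k += 1
                    i += 1
                else:
                    tmp[k] = y
                    k += 1
                    j += 1
            while i < cur_len:
                tmp[k] = cur[i]
                k += 1
                i += 1
            while j < len(other):
                tmp[k] = other[j]
                k += 1
                j += 1
            cur[:k] = tmp[:k]
            cur_len = k
    return pairs[:n_pairs]


def _triangle_table(dm: np.ndarray, max_filtration: float):
    """Enumerate triangles with diameter <= max_filtration.

    Returns (tri_idx (T,3) vertex indices, diam (T,)) unsorted."""
    n = dm.shape[0]
    tris = []
    diams = []
    for i in range(n - 2):
        d_ij = dm[i, i + 1:]          # j > i
        sub = dm[i + 1:, i + 1:]
        jj, kk = np.triu_indices(n - i - 1, k=1)
        diam = np.maximum(np.maximum(d_ij[jj], d_ij[kk]), sub[jj, kk])
        keep = diam <= max_filtration
        if not np.any(keep):
            continue
        jj, kk, diam = jj[keep], kk[keep], diam[keep]
        t = np.column_stack([np.full(len(jj), i), jj + i + 1, kk + i + 1])
        tris.append(t)
        diams.append(diam)
    if not tris:
        return np.empty((0, 3), np.int64), np.empty(0)
    return np.concatenate(tris).astype(np.int64), np.concatenate(diams)


def enclosing_radius(dm: np.ndarray) -> float:
    """min over points of the max distance to any other point."""
    return float(dm.max(axis=1).min())


def rips_persistence(points: PointSet, max_dim: int = 1,
                     max_filtration: float | None = None) -> PersistenceDiagram:
    """Persistence diagram (H0, H1) of the Rips filtration of a 3D cloud.

    ``max_filtration=None`` computes the complete filtration's diagram
    (truncating internally at the enclosing radius, which is exact).  An
    explicit cap truncates the filtration at that scale: classes alive at
    the cap become essential.
    """
    pts = points.points if isinstance(points, PointSet) else np.asarray(points, float)
    n = len(pts)
    if n < 2:
        raise DegenerateInputError("persistence needs at least 2 points")
    dm = squareform(pdist(pts))

    complete = max_filtration is None
    cap = enclosing_radius(dm) if complete else float(max_filtration)

    diagram = PersistenceDiagram()

    # --- H0: single-linkage merge heights = MST edge lengths
    mst = minimum_spanning_tree(dm)
    deaths = np.sort(mst.data)
    if complete:
        h0 = np.column_stack([np.zeros(n - 1), deaths])
        diagram.intervals[0] = h0
        diagram.essential[0] = np.zeros(1)
    else:
        fin = deaths[deaths <= cap]
        diagram.intervals[0] = np.column_stack([np.zeros(len(fin)), fin])
        diagram.essential[0] = np.zeros(n - len(fin))

    if max_dim < 1:
        return diagram

    # --- H1 via triangle-column reduction
    iu, ju = np.triu_indices(n, k=1)
    elen = dm[iu, ju]
    keep = elen <= cap
    iu, ju, elen = iu[keep], ju[keep], elen[keep]
    order = np.lexsort((ju, iu, elen))          # filtration order, deterministic ties
    e_i, e_j, e_len = iu[order], ju[order], elen[order]
    # edge (i, j) -> rank lookup table
    rank = np.full((n, n), -1, dtype=np.int64)
    rank[e_i, e_j] = np.arange(len(e_i))
    rank[e_j, e_i] = rank[e_i, e_j]

    tri_idx, tri_diam = _triangle_table(dm, cap)
    h1 = np.empty((0, 2))
    births_unpaired = []
    pairs = np.empty((0, 2), dtype=np.int64)
    if len(tri_idx):
        t_order = np.lexsort((tri_idx[:, 2], tri_idx[:, 1], tri_idx[:, 0], tri_diam))
        tri_idx, tri_diam = tri_idx[t_order], tri_diam[t_order]
        tri_edges = np.column_stack([
            rank[tri_idx[:, 0], tri_idx[:, 1]],
            rank[tri_idx[:, 0], tri_idx[:, 2]],
            rank[tri_idx[:, 1], tri_idx[:, 2]],
        ])
        pairs = _reduce_triangle_columns(tri_edges, len(e_len))
        births = e_len[pairs[:, 0]]
        ddeaths = tri_diam[pairs[:, 1]]
        pos = ddeaths > births
        h1 = np.column_stack([births[pos], ddeaths[pos]])
        h1 = h1[np.lexsort((h1[:, 1], h1[:, 0]))]
    if not complete:
        # positive edges never paired are alive at the cap -> essential
        paired = np.zeros(len(e_len), dtype=bool)
        if len(pairs):
            paired[pairs[:, 0]] = True
        mst_set = {(min(int(a), int(b)), max(int(a), int(b)))
                   for a, b in zip(*mst.nonzero())}
        for rr in range(len(e_len)):
            if not paired[rr] and (int(e_i[rr]), int(e_j[rr])) not in mst_set:
                births_unpaired.append(e_len[rr])
    diagram.intervals[1] = h1
    diagram.essential[1] = np.asarray(births_unpaired, dtype=np.float64)
    return diagram


# ---------------------------------------------------------------------------
# Diagram summaries
# ---------------------------------------------------------------------------

def short_bars(diagram: PersistenceDiagram, q: int, lo: float = 0.0,
               hi: float = SHORT_BAR_HI_UM) -> int:
    """Number of finite intervals with lo < length <= hi in dimension q."""
    life = diagram.lifetimes(q)
    return int(np.sum((life > lo) & (life <= hi)))


def persistent_entropy(diagram: PersistenceDiagram, q: int,
                       shannon: bool = True) -> float:
    """Entropy of normalized bar lengths over finite intervals.

    With ``shannon=True`` (default) returns -sum p_i ln p_i >= 0; with
    ``shannon=False`` the raw signed sum p_i ln p_i."""
    life = diagram.lifetimes(q)
    life = life[life > 0]
    if len(life) == 0:
        raise UndefinedFeatureError(
            f"persistent entropy undefined: no finite positive bars in H{q}")
    p = life / life.sum()
    h = -float(np.sum(p * np.log(p)))
    return h if shannon else -h


def landscape_layer1(diagram: PersistenceDiagram, q: int,
                     grid_size: int = LANDSCAPE_GRID):
    """Sample the first persistence landscape layer on a uniform grid over
    the diagram's filtration range.  Returns (grid, lambda_1 values)."""
    d = diagram.dim(q)
    if len(d) == 0:
        g = np.linspace(0.0, 1.0, grid_size)
        return g, np.zeros(grid_size)
    lo, hi = float(d[:, 0].min()), float(d[:, 1].max())
    if hi <= lo:
        hi = lo + 1.0
    g = np.linspace(lo, hi, grid_size)
    # tent g_(b,d)(x) = min(x - b, d - x) clipped at 0
    tents = np.minimum(g[None, :] - d[:, 0][:, None],
                       d[:, 1][:, None] - g[None, :])
    lam1 = np.maximum(tents.max(axis=0), 0.0)
    return g, lam1


def landscape_amplitude(diagram: PersistenceDiagram, q: int,
                        grid_size: int = LANDSCAPE_GRID) -> float:
    """L2 norm (trapezoid rule) of the first landscape layer."""
    if len(diagram.dim(q)) == 0:
        return 0.0
    g, lam1 = landscape_layer1(diagram, q, grid_size)
    return float(np.sqrt(np.trapezoid(lam1 ** 2, g)))


def persistence_image(diagram: PersistenceDiagram, q: int,
                      resolution: int = IMAGE_RESOLUTION,
                      bandwidth: float | None = None):
    """Gaussian raster of the diagram in birth–persistence coordinates with
    linear persistence weighting.  Returns the (resolution, resolution)
    image; an empty diagram yields a zero raster."""
    d = diagram.dim(q)
    img = np.zeros((resolution, resolution))
    if len(d) == 0:
        return img
    birth = d[:, 0]
    pers = d[:, 1] - d[:, 0]
    b_lo, b_hi = float(birth.min()), float(birth.max())
    p_lo, p_hi = 0.0, float(pers.max())
    rng_b = max(b_hi - b_lo, 1e-12)
    rng_p = max(p_hi - p_lo, 1e-12)
    if bandwidth is None:
        bandwidth = IMAGE_BANDWIDTH_FRACTION * max(rng_b, rng_p)
    bandwidth = max(bandwidth, 1e-12)
    gb = np.linspace(b_lo, b_hi, resolution)
    gp = np.linspace(p_lo, p_hi, resolution)
    # separable unnormalized-Gaussian evaluation with linear persistence
    # weighting; keeping the kernel unnormalized makes the raster (and its
    # L2 amplitude) scale linearly with the coordinates
    kb = np.exp(-0.5 * ((gb[None, :] - birth[:, None]) / bandwidth) ** 2)
    kp = np.exp(-0.5 * ((gp[None, :] - pers[:, None]) / bandwidth) ** 2)
    img = (kp * pers[:, None]).T @ kb         # rows: persistence, cols: birth
    return img


def image_amplitude(diagram: PersistenceDiagram, q: int,
                    resolution: int = IMAGE_RESOLUTION,
                    bandwidth: float | None = None) -> float:
    """L2 norm of the flattened persistence-image raster."""
    img = persistence_image(diagram, q, resolution, bandwidth)
    return float(np.linalg.norm(img.ravel()))


def wasserstein_amplitude(diagram: PersistenceDiagram, q: int, p: float = 2.0) -> float:
    """(sqrt2/2) * (sum of bar lengths^p)^(1/p) over finite intervals."""
    life = diagram.lifetimes(q)
    if len(life) == 0:
        return 0.0
    return float(np.sqrt(2) / 2 * np.sum(life ** p) ** (1.0 / p))


def bottleneck_amplitude(diagram: PersistenceDiagram, q: int) -> float:
    """(sqrt2/2) * longest bar length over finite intervals."""
    life = diagram.lifetimes(q)
    if len(life) == 0:
        return 0.0
    return float(np.sqrt(2) / 2 * life.max())


@dataclass
class TopoConfig:
    """Knobs for the topological feature vector.

    ``n_subsample`` is the cloud size the diagram is computed on (H0 runs on
    the full subsample via its minimum spanning tree).  ``h1_subsample``
    bounds the cloud used for dimension-1 persistence, whose boundary-matrix
    reduction scales as n^3; None computes H1 on the full subsample.
    """

    n_subsample: int = DEFAULT_SUBSAMPLE
    h1_subsample: int | None = 150
    #: filtration cap for the H1 computation, µm.  Loop classes of interest
    #: (crown rings) live well below this scale; loops still alive at the
    #: cap become essential classes and are excluded from the summaries.
    h1_max_filtration: float | None = 250.0
    max_filtration: float | None = None
    landscape_grid: int = LANDSCAPE_GRID
    image_resolution: int = IMAGE_RESOLUTION
    image_bandwidth: float | None = None
    wasserstein_p: float = 2.0


def topo_feature_vector(points: PointSet, config: TopoConfig | None = None,
                        rng: np.random.Generator | int | None = 0) -> dict:
    """Subsample, run Rips persistence, and compute all 12 summaries in the
    fixed :data:`TOPO_FEATURE_NAMES` order.  An empty H1 diagram yields 0
    for its entropy (no bars carries no information), matching the other
    summaries' empty-diagram convention."""
    cfg = config or TopoConfig()
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sub = subsample_points(points, cfg.n_subsample, rng)
    dgm = rips_persistence(sub, max_dim=0, max_filtration=cfg.max_filtration)
    if cfg.h1_subsample is not None and len(sub) > cfg.h1_subsample:
        sub1 = subsample_points(sub, cfg.h1_subsample, rng)
    else:
        sub1 = sub
    h1_cap = cfg.h1_max_filtration if cfg.h1_max_filtration is not None \
        else cfg.max_filtration
    dgm1 = rips_persistence(sub1, max_dim=1, max_filtration=h1_cap)
    dgm.intervals[1] = dgm1.intervals[1]
    dgm.essential[1] = dgm1.essential[1]
    out = {}
    for q in (0, 1):
        tag = f"h{q}"
        out[f"short_bars_{tag}"] = float(short_bars(dgm, q))
        try:
            out[f"persistent_entropy_{tag}"] = persistent_entropy(dgm, q)
        except UndefinedFeatureError:
            out[f"persistent_entropy_{tag}"] = 0.0
        out[f"amp_landscape_{tag}"] = landscape_amplitude(dgm, q, cfg.landscape_grid)
        out[f"amp_image_{tag}"] = image_amplitude(dgm, q, cfg.image_resolution,
                                                  cfg.image_bandwidth)
        out[f"amp_wasserstein_{tag}"] = wasserstein_amplitude(dgm, q, cfg.wasserstein_p)
        out[f"amp_bottleneck_{tag}"] = bottleneck_amplitude(dgm, q)
    return {k: out[k] for k in TOPO_FEATURE_NAMES}


def diagram_to_csv(diagram: PersistenceDiagram, path) -> None:
    """Serialize finite intervals as CSV rows (dim, birth, death)."""
    rows = []
    for q in sorted(diagram.intervals):
        for b, d in diagram.dim(q):
            rows.append(f"{q},{b!r},{d!r}")
    with open(path, "w") as fh:
        fh.write("dim,birth,death\n")
        fh.write("\n".join(rows) + ("\n" if rows else ""))
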