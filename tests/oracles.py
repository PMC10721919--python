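"""Independent brute-force oracles used by the test suite.

These deliberately share no code with the package: persistence via full
boundary-matrix reduction over all simplices, MSTs via Kruskal (networkx),
connectivity via a hand-rolled BFS.
"""

import itertools

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist, squareform


def brute_force_rips(pts):
    """Full boundary-matrix reduction of the Rips filtration (dims 0-2).

    Returns {0: (n,2) array, 1: (m,2) array} of finite (birth, death) pairs
    with positive persistence, sorted lexicographically.
    """
    n = len(pts)
    dm = squareform(pdist(pts))
    simplices = [((i,), 0.0) for i in range(n)]
    for i, j in itertools.combinations(range(n), 2):
        simplices.append(((i, j), dm[i, j]))
    for i, j, k in itertools.combinations(range(n), 3):
        simplices.append(((i, j, k), max(dm[i, j], dm[i, k], dm[j, k])))
    simplices.sort(key=lambda s: (s[1], len(s[0]), s[0]))
    index = {s[0]: idx for idx, s in enumerate(simplices)}
    cols = []
    for s, _ in simplices:
        if len(s) == 1:
            cols.append(set())
        else:
            cols.append({index[tuple(sorted(f))]
                         for f in itertools.combinations(s, len(s) - 1)})
    low = {}
    pairs = []
    for j, col in enumerate(cols):
        while col:
            piv = max(col)
            if piv in low:
                col ^= cols[low[piv]]
            else:
                low[piv] = j
                pairs.append((piv, j))
                break
    dgm = {0: [], 1: []}
    for piv, j in pairs:
        q = len(simplices[piv][0]) - 1
        b, d = simplices[piv][1], simplices[j][1]
        if q in dgm and d > b:
            dgm[q].append((b, d))
    return {q: np.array(sorted(v)) if v else np.empty((0, 2))
            for q, v in dgm.items()}


def kruskal_mst_weights(pts):
    """Sorted MST edge weights via networkx Kruskal."""
    n = len(pts)
    dm = squareform(pdist(pts))
    g = nx.Graph()
    for i in range(n):
        for j in range(i + 1, n):
            g.add_edge(i, j, weight=dm[i, j])
    t = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return np.sort([d["weight"] for _, _, d in t.edges(data=True)])


def bfs_component(edges, subset, seed):
    """Vertices of ``subset`` reachable from ``seed`` via edges inside it."""
    subset = set(int(v) for v in subset)
    adj = {}
    for a, b in edges:
        a, b = int(a), int(b)
        if a in subset and b in subset:
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
    seen = {int(seed)}
    stack = [int(seed)]
    while stack:
        u = stack.pop()
        for w in adj.get(u, ()):
            if w not in seen:
                seen.add(w)
                stack.append(w)
    return np.array(sorted(seen))
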