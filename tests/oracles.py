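"""Independent brute-force reference implementations used only by tests.

Each oracle deliberately takes a different algorithmic route from the package
code it checks: union-find for connected components, per-voxel scans for
morphology, exhaustive subset enumeration for the robust location/scale
estimate, and an explicit sparse-graph Dijkstra for geodesic distances.
"""

import itertools
import math

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import dijkstra as _csgraph_dijkstra

_OFFSETS_26 = [
    (dx, dy, dz)
    for dx in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dz in (-1, 0, 1)
    if (dx, dy, dz) != (0, 0, 0)
]
_OFFSETS_6 = [o for o in _OFFSETS_26 if sum(abs(c) for c in o) == 1]


def union_find_components(data: np.ndarray, connectivity: int):
    """Partition of true voxels into connected sets, as a set of frozensets."""
    offsets = _OFFSETS_6 if connectivity == 6 else _OFFSETS_26
    voxels = [tuple(v) for v in np.argwhere(data)]
    parent = {v: v for v in voxels}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    vox_set = set(voxels)
    for v in voxels:
        for o in offsets:
            w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if w in vox_set:
                parent[find(v)] = find(w)
    groups: dict = {}
    for v in voxels:
        groups.setdefault(find(v), []).append(v)
    return {frozenset(g) for g in groups.values()}


def erode_bruteforce(data: np.ndarray) -> np.ndarray:
    """One 3x3x3 erosion; outside the grid counts as background."""
    out = np.zeros_like(data)
    for v in np.argwhere(data):
        ok = True
        for o in _OFFSETS_26:
            w = v + o
            if np.any(w < 0) or np.any(w >= data.shape) or not data[tuple(w)]:
                ok = False
                break
        out[tuple(v)] = ok
    return out


def fill_holes_bruteforce(data: np.ndarray) -> np.ndarray:
    """Fill background cavities not 6-connected to the border, by flood fill."""
    reach = np.zeros_like(data)
    stack = [tuple(v) for v in np.argwhere(~data) if 0 in v or any(v[i] == data.shape[i] - 1 for i in range(3))]
    for v in stack:
        reach[v] = True
    while stack:
        v = stack.pop()
        for o in _OFFSETS_6:
            w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
            if all(0 <= w[i] < data.shape[i] for i in range(3)) and not data[w] and not reach[w]:
                reach[w] = True
                stack.append(w)
    # reach is False on every foreground voxel, so ~reach = foreground + cavities
    return data | ~reach


def bbox_volume_bruteforce(voxels: np.ndarray) -> int:
    lo = voxels.min(axis=0)
    hi = voxels.max(axis=0)
    return int(np.prod(hi - lo + 1))


def exhaustive_mcd(x, support_fraction: float):
    """Raw minimal-variance h-subset statistics by full subset enumeration."""
    x = np.asarray(x, dtype=np.float64)
    n = x.size
    h = int(math.ceil(support_fraction * n))
    best_var = np.inf
    best_mu = None
    for idx in itertools.combinations(range(n), h):
        sub = x[list(idx)]
        var = float(np.var(sub))
        if var < best_var:
            best_var = var
            best_mu = float(np.mean(sub))
    return best_mu, math.sqrt(best_var)


def dijkstra_distance(seed_data: np.ndarray, domain_data: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Multi-source shortest paths on the explicit 26-neighbour weighted graph.

    A virtual source node connected to every seed voxel with zero-weight edges
    turns the multi-source problem into a single Dijkstra run.
    """
    trav = domain_data | seed_data
    shape = trav.shape
    flat = np.flatnonzero(trav.ravel())
    node_of = -np.ones(trav.size, dtype=np.int64)
    node_of[flat] = np.arange(flat.size)
    n_nodes = flat.size + 1  # last node = virtual source
    spacing = np.asarray(spacing, dtype=np.float64)
    lin = np.arange(trav.size).reshape(shape)
    rows, cols, weights = [], [], []
    for off in _OFFSETS_26:
        src_sl = tuple(slice(max(0, -d), shape[i] - max(0, d)) for i, d in enumerate(off))
        dst_sl = tuple(slice(max(0, d), shape[i] - max(0, -d)) for i, d in enumerate(off))
        pair = trav[src_sl] & trav[dst_sl]
        a = node_of[lin[src_sl][pair]]
        b = node_of[lin[dst_sl][pair]]
        w = float(np.linalg.norm(np.asarray(off) * spacing))
        rows.append(a)
        cols.append(b)
        weights.append(np.full(a.size, w))
    seed_nodes = node_of[lin[seed_data]]
    rows.append(np.full(seed_nodes.size, n_nodes - 1))
    cols.append(seed_nodes)
    weights.append(np.zeros(seed_nodes.size))
    graph = sp.csr_matrix(
        (np.concatenate(weights), (np.concatenate(rows), np.concatenate(cols))), shape=(n_nodes, n_nodes)
    )
    dist = _csgraph_dijkstra(graph, directed=True, indices=n_nodes - 1)
    out = np.full(shape, np.inf)
    out.ravel()[flat] = dist[:-1]
    return out
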