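"""k-nearest-neighbor graphs and hitting-time pseudotime.

Pseudotime is the expected number of steps a uniform random walk started at
a cell takes to first hit the origin population on the symmetrized kNN
graph.  Writing h(v) for that expectation, h = 0 on the origin and
h(v) = 1 + mean over neighbors u of h(u) elsewhere; in matrix form the free
block satisfies the grounded-Laplacian system (D - A) h = d, which is
symmetric positive definite and solved exactly (sparse direct solve, or
conjugate gradients for large graphs).

Expert endpoints are supported by recomputing pseudotime as the commute
fraction t(v) = h_O(v) / (h_O(v) + h_E(v)) where h_O / h_E are hitting
times to the origin / endpoint sets.  This pins t = 0 on the origin and
t = 1 on the endpoints, so after orientation every endpoint is a sink and
dead-end side branches drain back toward the designated ends -- the fix for
origin-anchored pseudotime "shortcuts" that leave a distal population
unreachable by walks.

Orientation turns each undirected edge {u, v} into u -> v iff
(t(u), u) < (t(v), v) lexicographically; the injective total order makes
the result a DAG with deterministic tie-breaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from sklearn.neighbors import NearestNeighbors

from .fcs import EventTable

__all__ = [
    "KnnGraph",
    "PseudotimeField",
    "OrientedGraph",
    "build_knn_graph",
    "compute_pseudotime",
    "recompute_pseudotime_with_endpoints",
    "orient_edges",
    "hitting_times",
]

logger = logging.getLogger(__name__)

# Above this many free vertices the SPD hitting-time system is solved by
# conjugate gradients instead of a sparse direct factorization.
_DIRECT_SOLVE_LIMIT = 12_000


@dataclass
class KnnGraph:
    """Symmetrized k-nearest-neighbor graph over events.

    ``adjacency`` is the symmetric sparse matrix of edge distances (union of
    per-vertex neighbor lists).  ``n_repair_edges`` counts bridges added to
    connect components; repairs change topology and are logged loudly.
    """

    n_vertices: int
    k: int
    metric: str
    neighbor_indices: np.ndarray  # (n, k) nearest neighbors, self excluded
    neighbor_distances: np.ndarray
    adjacency: sp.csr_matrix
    n_repair_edges: int = 0

    def degrees(self) -> np.ndarray:
        return np.diff(self.adjacency.indptr)


@dataclass
class PseudotimeField:
    """One nonnegative scalar per vertex; 0 exactly on the origin set."""

    t: np.ndarray
    mode: str  # "hitting_time" | "endpoint_normalized"
    origin: np.ndarray
    endpoints: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.t)):
            raise ValueError("pseudotime contains non-finite values")
        if self.mode not in ("hitting_time", "endpoint_normalized"):
            raise ValueError(f"unknown pseudotime mode {self.mode!r}")


@dataclass
class OrientedGraph:
    """Pseudotime-directed DAG: CSR out-adjacency plus sink flags."""

    n_vertices: int
    indptr: np.ndarray
    indices: np.ndarray
    sinks: np.ndarray  # bool, out-degree == 0
    order_key: np.ndarray  # pseudotime component of the orientation order
    order_aux: np.ndarray | None = None  # plateau escape-depth component

    def out_degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def out_neighbors(self, v: int) -> np.ndarray:
        return self.indices[self.indptr[v] : self.indptr[v + 1]]


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def _as_matrix(table: EventTable | np.ndarray) -> np.ndarray:
    x = table.values if isinstance(table, EventTable) else np.asarray(table, dtype=np.float64)
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    return x


def build_knn_graph(
    table: EventTable | np.ndarray,
    k: int = 30,
    metric: str = "euclidean",
) -> KnnGraph:
    """Exact k-nearest-neighbor graph, symmetrized by edge union.

    If the symmetrized graph is disconnected, components are bridged by the
    single shortest inter-component edge along a minimum-spanning forest of
    component centroids, so downstream hitting times are finite everywhere.
    """
    x = _as_matrix(table)
    n = x.shape[0]
    if k < 2:
        raise ValueError("k must be >= 2")
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of events ({n})")

    nn = NearestNeighbors(n_neighbors=k + 1, metric=metric, algorithm="auto")
    nn.fit(x)
    dist, idx = nn.kneighbors(x)
    # Drop the self column wherever it appears (ties can displace it from 0).
    keep_idx = np.empty((n, k), dtype=np.int64)
    keep_dist = np.empty((n, k), dtype=np.float64)
    rows = np.arange(n)
    self_col = np.argmax(idx == rows[:, None], axis=1)
    has_self = idx[rows, self_col] == rows
    for i in range(n):
        if has_self[i]:
            sel = np.concatenate([np.arange(self_col[i]), np.arange(self_col[i] + 1, k + 1)])
        else:
            sel = np.arange(k)
        keep_idx[i] = idx[i, sel]
        keep_dist[i] = dist[i, sel]

    rows_rep = np.repeat(rows, k)
    a = sp.csr_matrix((keep_dist.ravel() + 1e-300, (rows_rep, keep_idx.ravel())), shape=(n, n))
    adjacency = a.maximum(a.T).tocsr()

    n_comp, labels = connected_components(adjacency, directed=False)
    n_repair = 0
    if n_comp > 1:
        adjacency, n_repair = _repair_connectivity(adjacency, x, labels, n_comp)
        logger.warning(
            "kNN graph had %d components; added %d bridge edge(s) to connect it "
            "(this changes the topology)",
            n_comp,
            n_repair,
        )
    return KnnGraph(
        n_vertices=n,
        k=k,
        metric=metric,
        neighbor_indices=keep_idx,
        neighbor_distances=keep_dist,
        adjacency=adjacency,
        n_repair_edges=n_repair,
    )


def _repair_connectivity(
    adjacency: sp.csr_matrix, x: np.ndarray, labels: np.ndarray, n_comp: int
) -> tuple[sp.csr_matrix, int]:
    centroids = np.stack([x[labels == c].mean(axis=0) for c in range(n_comp)])
    d2 = ((centroids[:, None, :] - centroids[None, :, :]) ** 2).sum(-1)
    mst = minimum_spanning_tree(sp.csr_matrix(np.sqrt(d2)))
    lil = adjacency.tolil()
    n_repair = 0
    ci, cj = mst.nonzero()
    for a, b in zip(ci, cj):
        pa = np.flatnonzero(labels == a)
        pb = np.flatnonzero(labels == b)
        # closest cross-component pair (exact; component sizes are modest
        # whenever repair is needed at all)
        d = ((x[pa][:, None, :] - x[pb][None, :, :]) ** 2).sum(-1)
        u, v = np.unravel_index(np.argmin(d), d.shape)
        w = float(np.sqrt(d[u, v])) + 1e-300
        lil[pa[u], pb[v]] = w
        lil[pb[v], pa[u]] = w
        n_repair += 1
    return lil.tocsr(), n_repair


# ---------------------------------------------------------------------------
# Hitting times and pseudotime
# ---------------------------------------------------------------------------


def _validate_vertex_set(name: str, s, n: int) -> np.ndarray:
    s = np.unique(np.asarray(list(s) if not isinstance(s, np.ndarray) else s, dtype=np.int64))
    if s.size == 0:
        raise ValueError(f"{name} set is empty")
    if s.min() < 0 or s.max() >= n:
        raise ValueError(f"{name} set contains out-of-range vertex indices")
    return s


def hitting_times(graph: KnnGraph, absorbing: np.ndarray) -> np.ndarray:
    """Expected steps of a uniform-neighbor random walk to first hit ``absorbing``.

    Solves the grounded Laplacian system (D - A) h = d on the free vertices
    with the unweighted symmetrized adjacency; exact up to solver tolerance.
    """
    n = graph.n_vertices
    absorbing = _validate_vertex_set("absorbing", absorbing, n)
    free = np.setdiff1d(np.arange(n), absorbing, assume_unique=False)
    h = np.zeros(n)
    if free.size == 0:
        return h
    adj = graph.adjacency.copy()
    adj.data = np.ones_like(adj.data)  # uniform transitions: unweighted adjacency
    deg = np.asarray(adj.sum(axis=1)).ravel()
    lap = sp.diags(deg) - adj
    lap_ff = lap[free][:, free].tocsr()
    rhs = deg[free]
    if free.size <= _DIRECT_SOLVE_LIMIT:
        h_free = sp.linalg.spsolve(lap_ff.tocsc(), rhs)
    else:
        ml = sp.diags(1.0 / lap_ff.diagonal())
        h_free, info = sp.linalg.cg(lap_ff, rhs, M=ml, rtol=1e-12, atol=0.0, maxiter=50_000)
        if info != 0:
            raise RuntimeError(f"conjugate-gradient hitting-time solve did not converge (info={info})")
    h[free] = h_free
    return h


def compute_pseudotime(graph: KnnGraph, origin) -> PseudotimeField:
    """Origin-anchored pseudotime: expected hitting time to the origin set."""
    origin = _validate_vertex_set("origin", origin, graph.n_vertices)
    t = hitting_times(graph, origin)
    return PseudotimeField(t=t, mode="hitting_time", origin=origin)


def recompute_pseudotime_with_endpoints(
    graph: KnnGraph, origin, endpoints
) -> PseudotimeField:
    """Endpoint-normalized pseudotime t = h_O / (h_O + h_E) in [0, 1].

    t = 0 exactly on the origin and t = 1 exactly on the expert endpoints,
    which after orientation forces every designated endpoint to be a sink.
    """
    n = graph.n_vertices
    origin = _validate_vertex_set("origin", origin, n)
    endpoints = _validate_vertex_set("endpoints", endpoints, n)
    if np.intersect1d(origin, endpoints).size:
        raise ValueError("origin and endpoint sets overlap")
    h_o = hitting_times(graph, origin)
    h_e = hitting_times(graph, endpoints)
    denom = h_o + h_e
    t = np.zeros(n)
    nz = denom > 0
    t[nz] = h_o[nz] / denom[nz]
    t[origin] = 0.0
    t[endpoints] = 1.0
    return PseudotimeField(t=t, mode="endpoint_normalized", origin=origin, endpoints=endpoints)


# ---------------------------------------------------------------------------
# Orientation
# ---------------------------------------------------------------------------


def _origin_escape_depth(graph: KnnGraph, origin: np.ndarray) -> np.ndarray:
    """Hop distance of each origin vertex to the nearest non-origin vertex.

    The origin set is a flat t = 0 plateau; orienting its internal edges by
    the raw index tie-break would strand walks at spurious interior sinks.
    Ordering plateau vertices by decreasing escape depth instead guarantees
    every origin vertex keeps an out-edge toward the plateau boundary.
    """
    n = graph.n_vertices
    in_origin = np.zeros(n, dtype=bool)
    in_origin[origin] = True
    depth = np.zeros(n)
    frontier = np.flatnonzero(~in_origin)
    seen = ~in_origin
    level = 0
    indptr, indices = graph.adjacency.indptr, graph.adjacency.indices
    while frontier.size and not seen.all():
        level += 1
        nxt = np.unique(indices[np.concatenate([np.arange(indptr[f], indptr[f + 1]) for f in frontier])])
        nxt = nxt[~seen[nxt]]
        depth[nxt] = level
        seen[nxt] = True
        frontier = nxt
    depth[~seen] = level + 1  # origin-only components: deepest
    return depth


def orient_edges(graph: KnnGraph, pt: PseudotimeField) -> OrientedGraph:
    """Direct each undirected edge toward larger (pseudotime, index); a DAG.

    The injective total order is lexicographic (t, -escape depth, index):
    within the zero-pseudotime origin plateau, vertices deeper inside the
    plateau come first, so oriented edges lead out of the origin; elsewhere
    pseudotime decides and the vertex index breaks exact ties.
    """
    n = graph.n_vertices
    if pt.t.shape != (n,):
        raise ValueError("pseudotime not defined on all vertices")
    aux = -_origin_escape_depth(graph, pt.origin) if pt.origin is not None else np.zeros(n)
    coo = sp.triu(graph.adjacency, k=1).tocoo()
    u, v = coo.row, coo.col
    tu, tv, au, av = pt.t[u], pt.t[v], aux[u], aux[v]
    forward = (tu < tv) | ((tu == tv) & ((au < av) | ((au == av) & (u < v))))
    src = np.where(forward, u, v)
    dst = np.where(forward, v, u)
    directed = sp.csr_matrix((np.ones(src.size, dtype=np.int8), (src, dst)), shape=(n, n))
    directed.sum_duplicates()
    out_deg = np.diff(directed.indptr)
    return OrientedGraph(
        n_vertices=n,
        indptr=directed.indptr.copy(),
        indices=directed.indices.copy(),
        sinks=out_deg == 0,
        order_key=pt.t.copy(),
        order_aux=aux,
    )
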