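"""Pseudotime-directed random walks and endpoint detection.

Walks start at a uniformly chosen origin cell and step uniformly over the
outgoing edges of the pseudotime-oriented kNN graph until they reach a sink
(a cell with no outgoing edges).  Sinks are the automatically detected
developmental endpoints; sinks reached by enough walks are grouped by
graph-hop proximity into endpoint groups, and walks can then be selected by
the group their terminal belongs to.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.csgraph import breadth_first_order, connected_components

from .graph import KnnGraph, OrientedGraph

__all__ = [
    "Walk",
    "WalkSet",
    "EndpointGroup",
    "simulate_walks",
    "detect_endpoint_groups",
    "select_walks",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Walk:
    vertices: np.ndarray

    @property
    def terminal(self) -> int:
        return int(self.vertices[-1])

    def __len__(self) -> int:
        return len(self.vertices)


@dataclass
class WalkSet:
    """A reproducible batch of simulated walks."""

    walks: list[Walk]
    seed: int
    n_requested: int

    def __post_init__(self) -> None:
        if len(self.walks) != self.n_requested:
            raise ValueError("walk count does not match n_requested")

    def __len__(self) -> int:
        return len(self.walks)

    def __getitem__(self, i: int) -> Walk:
        return self.walks[i]

    @property
    def terminals(self) -> np.ndarray:
        return np.array([w.terminal for w in self.walks], dtype=np.int64)


@dataclass
class EndpointGroup:
    """A cluster of nearby sinks and the walks terminating in them."""

    name: str
    sinks: frozenset[int]
    member_walks: np.ndarray

    @property
    def n_walks(self) -> int:
        return len(self.member_walks)


def simulate_walks(
    g: OrientedGraph,
    origin,
    n_walks: int = 5000,
    seed: int = 0,
) -> WalkSet:
    """Simulate ``n_walks`` random walks on the oriented graph.

    Each walk starts at a uniformly chosen origin vertex and, at every step,
    moves to a uniformly chosen out-neighbor until it reaches a sink.  A walk
    started on a sink terminates immediately as a length-1 walk.  Fully
    deterministic given (graph, origin, seed): a single generator drives
    start choices and all steps in a fixed order.
    """
    if n_walks <= 0:
        raise ValueError("n_walks must be positive")
    origin = np.unique(np.asarray(list(origin), dtype=np.int64))
    if origin.size == 0:
        raise ValueError("origin set is empty")
    rng = np.random.default_rng(seed)
    starts = origin[rng.integers(0, origin.size, size=n_walks)]
    if g.sinks[starts].any():
        logger.info(
            "%d walk(s) start on a sink and terminate immediately",
            int(g.sinks[starts].sum()),
        )

    out_deg = g.out_degree()
    paths: list[list[int]] = [[int(s)] for s in starts]
    active = np.flatnonzero(out_deg[starts] > 0)
    pos = starts.copy()
    while active.size:
        cur = pos[active]
        deg = out_deg[cur]
        step = (rng.random(active.size) * deg).astype(np.int64)
        step = np.minimum(step, deg - 1)
        nxt = g.indices[g.indptr[cur] + step]
        pos[active] = nxt
        for w, v in zip(active, nxt):
            paths[w].append(int(v))
        active = active[out_deg[nxt] > 0]
    return WalkSet(
        walks=[Walk(np.array(p, dtype=np.int64)) for p in paths],
        seed=seed,
        n_requested=n_walks,
    )


def detect_endpoint_groups(
    ws: WalkSet,
    g: KnnGraph,
    min_walks: int = 10,
    hop_radius: int = 2,
) -> list[EndpointGroup]:
    """Group well-supported sinks into endpoint groups by hop proximity.

    Sinks reached by at least ``min_walks`` walks are merged by single
    linkage over undirected hop distance <= ``hop_radius`` on the kNN graph.
    Groups are named "EG1", "EG2", ... by descending member-walk count
    (ties by smallest sink index), deterministically.
    """
    terminals = ws.terminals
    sink_ids, counts = np.unique(terminals, return_counts=True)
    qualified = sink_ids[counts >= min_walks]
    if qualified.size == 0:
        logger.warning(
            "no sink reached by >= %d walks; no endpoint groups detected", min_walks
        )
        return []

    # vertices within hop_radius of any qualified sink, via boolean sparse powers
    adj = g.adjacency.astype(bool)
    reach = sp.identity(g.n_vertices, dtype=bool, format="csr")[qualified]
    ball = reach.copy()
    for _ in range(hop_radius):
        reach = reach @ adj
        ball = ball + reach
    # two sinks are linked iff their hop distance <= hop_radius, i.e. sink j
    # lies in the radius-r ball around sink i
    link = ball[:, qualified].toarray()
    link = link | link.T
    n_comp, labels = connected_components(sp.csr_matrix(link), directed=False)

    groups = []
    for c in range(n_comp):
        sinks = frozenset(int(s) for s in qualified[labels == c])
        members = np.flatnonzero(np.isin(terminals, list(sinks)))
        groups.append((sinks, members))
    groups.sort(key=lambda g_: (-len(g_[1]), min(g_[0])))
    return [
        EndpointGroup(name=f"EG{i + 1}", sinks=s, member_walks=m)
        for i, (s, m) in enumerate(groups)
    ]


def select_walks(ws: WalkSet, group: EndpointGroup) -> WalkSet:
    """Sub-WalkSet of walks whose terminal lies in the group; order preserved."""
    members = [ws.walks[i] for i in group.member_walks]
    return WalkSet(walks=members, seed=ws.seed, n_requested=len(members))
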