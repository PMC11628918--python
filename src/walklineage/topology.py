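"""Topological classification of walks via persistent homology.

Two walks from the origin to the same endpoint region can still be
biologically different routes if the point cloud has a hole (an H1 class)
and the walks pass on opposite sides of it.  This module makes that notion
computable:

1. a landmark subset of events is chosen by greedy farthest-point (maxmin)
   sampling, and every event is assigned to its nearest landmark;
2. Vietoris-Rips persistence of the landmark cloud is computed up to
   dimension 1 with mod-2 coefficients (own matrix-reduction implementation,
   with representative cycles);
3. significant H1 classes are selected from the diagram (by persistence
   ratio or top-k) together with a single working scale epsilon at which all
   of them are alive;
4. each walk is mapped to its landmark itinerary, closed into a loop through
   a fixed origin landmark by shortest paths in the epsilon-complex, and the
   loop's mod-2 homology coordinates over the significant classes become the
   walk's binary signature (XOR-additive by construction);
5. signatures plus terminal identity feed an average-linkage dendrogram from
   which topologically coherent trajectory bundles are cut.

The mod-2 linear algebra uses Python integers as bit vectors; reduction is
the standard persistence "low" pairing.  A cycle is expressed in homology
coordinates by greedy elimination against a basis of the cycle space whose
elements all have distinct leading edges: boundaries and representatives of
non-significant classes carry a zero tag, significant representatives carry
their class bit, and the XOR of tags accumulated while reducing a cycle to
zero is exactly its signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.cluster.hierarchy import cut_tree, leaves_list, linkage
from scipy.sparse.csgraph import breadth_first_order
from scipy.spatial.distance import pdist, squareform

from .fcs import EventTable
from .walks import Walk, WalkSet

__all__ = [
    "LandmarkSet",
    "PersistenceDiagram",
    "RipsResult",
    "SignificantClasses",
    "H1Basis",
    "WalkSignature",
    "WalkDendrogram",
    "select_landmarks",
    "compute_persistence",
    "significant_classes",
    "h1_basis",
    "walk_signature",
    "walk_signatures",
    "cluster_walks",
    "dominant_landmark",
]


# ---------------------------------------------------------------------------
# Landmarks
# ---------------------------------------------------------------------------


@dataclass
class LandmarkSet:
    indices: np.ndarray  # landmark vertex indices, in selection order
    assignment: np.ndarray  # nearest-landmark index (into `indices`) per vertex
    seed: int
    coordinates: np.ndarray  # landmark coordinates, row-aligned with `indices`


def select_landmarks(table: EventTable | np.ndarray, count: int = 500, seed: int = 0) -> LandmarkSet:
    """Greedy farthest-point (maxmin) landmark selection from a seeded start.

    The first landmark is a uniformly random vertex; each subsequent landmark
    is the vertex farthest from the current landmark set (ties to the lowest
    vertex index, via first-argmax).  Events are assigned to their nearest
    landmark, ties to the lower landmark index.
    """
    x = table.values if isinstance(table, EventTable) else np.asarray(table, dtype=np.float64)
    n = x.shape[0]
    if count <= 0:
        raise ValueError("landmark count must be positive")
    if count > n:
        raise ValueError(f"cannot select {count} landmarks from {n} events")
    rng = np.random.default_rng(seed)
    first = int(rng.integers(0, n))
    chosen = [first]
    d_min = np.linalg.norm(x - x[first], axis=1)
    for _ in range(count - 1):
        nxt = int(np.argmax(d_min))
        chosen.append(nxt)
        d_min = np.minimum(d_min, np.linalg.norm(x - x[nxt], axis=1))
    idx = np.array(chosen, dtype=np.int64)
    # nearest-landmark assignment; argmin returns the first (=lowest) index on ties
    assignment = np.empty(n, dtype=np.int64)
    block = max(1, 2_000_000 // max(1, count))
    for s in range(0, n, block):
        d = np.linalg.norm(x[s : s + block, None, :] - x[idx][None, :, :], axis=2)
        assignment[s : s + block] = np.argmin(d, axis=1)
    return LandmarkSet(indices=idx, assignment=assignment, seed=seed, coordinates=x[idx].copy())


def dominant_landmark(lm: LandmarkSet, vertices) -> int:
    """The landmark owning the most of the given vertices (ties: lowest index)."""
    owners = lm.assignment[np.asarray(list(vertices), dtype=np.int64)]
    counts = np.bincount(owners, minlength=len(lm.indices))
    return int(np.argmax(counts))


# ---------------------------------------------------------------------------
# Vietoris-Rips persistence (mod 2)
# ---------------------------------------------------------------------------


@dataclass
class PersistenceDiagram:
    """(birth, death) pairs per homology dimension, persistence-descending."""

    pairs: dict[int, np.ndarray]

    def persistence(self, dim: int) -> np.ndarray:
        p = self.pairs.get(dim, np.empty((0, 2)))
        return p[:, 1] - p[:, 0]


@dataclass
class RipsResult:
    """Diagram plus the internals needed to classify cycles.

    ``edges`` is the filtration-sorted (i, j, distance) array; an "edge
    position" is a row index into it.  ``reps`` maps each cycle-creating
    (positive) edge position to a representative mod-2 cycle, stored as a
    Python int whose set bits are edge positions; the representative of a
    class that dies within ``max_scale`` is the reduced boundary column at
    its death (hence a boundary in any complex containing its death scale),
    while a class still alive at ``max_scale`` keeps its birth cycle.
    """

    n_landmarks: int
    max_scale: float
    edges: np.ndarray  # (E, 3) float: i, j, distance, sorted by (d, i, j)
    diagram: PersistenceDiagram
    h1_classes: list[tuple[float, float, int]]  # (birth, death, birth edge position)
    reps: dict[int, int]
    h1_deaths: dict[int, float]  # birth edge position -> death scale (max_scale if alive)

    def edge_position(self, i: int, j: int) -> int | None:
        key = (min(i, j), max(i, j))
        return self._edge_lookup.get(key)

    def __post_init__(self) -> None:
        self._edge_lookup = {
            (int(min(a, b)), int(max(a, b))): pos
            for pos, (a, b, _) in enumerate(self.edges)
        }


def compute_persistence(
    lm: LandmarkSet | np.ndarray,
    max_scale: float,
    max_dim: int = 1,
) -> RipsResult:
    """Vietoris-Rips persistence of the landmark cloud up to ``max_dim`` (<= 1).

    Mod-2 coefficients; pairs that survive past ``max_scale`` are truncated
    at ``max_scale`` (dimension 0 keeps one infinite bar per final
    component).  Representative cycles are retained for every H1 class.
    """
    pts = lm.coordinates if isinstance(lm, LandmarkSet) else np.asarray(lm, dtype=np.float64)
    if not np.all(np.isfinite(pts)):
        raise ValueError("landmark coordinates contain non-finite values")
    if max_dim > 1:
        raise ValueError("persistence is implemented up to dimension 1")
    n = pts.shape[0]
    if n < 3:
        return RipsResult(
            n_landmarks=n,
            max_scale=max_scale,
            edges=np.empty((0, 3)),
            diagram=PersistenceDiagram({0: np.array([[0.0, np.inf]] * n), 1: np.empty((0, 2))}),
            h1_classes=[],
            reps={},
            h1_deaths={},
        )

    dm = squareform(pdist(pts))
    iu, ju = np.triu_indices(n, k=1)
    dv = dm[iu, ju]
    keep = dv <= max_scale
    order = np.lexsort((ju[keep], iu[keep], dv[keep]))
    ei, ej, ed = iu[keep][order], ju[keep][order], dv[keep][order]
    edges = np.column_stack([ei, ej, ed]).astype(np.float64)
    n_edges = len(ed)

    # --- reduce the vertex boundary matrix, tracking V to get birth cycles
    pivot_v: dict[int, tuple[int, int]] = {}  # vertex -> (reduced column, V column)
    birth_rep: dict[int, int] = {}  # positive edge position -> cycle bitset
    h0_deaths: list[float] = []
    for pos in range(n_edges):
        col = (1 << int(ei[pos])) | (1 << int(ej[pos]))
        v = 1 << pos
        while col:
            low = col.bit_length() - 1
            if low not in pivot_v:
                pivot_v[low] = (col, v)
                h0_deaths.append(ed[pos])
                break
            pc, pv = pivot_v[low]
            col ^= pc
            v ^= pv
        else:
            birth_rep[pos] = v

    h0_pairs = [(0.0, d) for d in h0_deaths]
    n_components = n - len(h0_deaths)
    h0_pairs += [(0.0, np.inf)] * n_components
    h0 = np.array(sorted(h0_pairs, key=lambda p: -(p[1] - p[0])))

    h1_classes: list[tuple[float, float, int]] = []
    reps: dict[int, int] = {}
    h1_deaths: dict[int, float] = {}
    if max_dim >= 1 and birth_rep:
        # --- enumerate triangles under max_scale via neighbor bitsets
        nbr = [0] * n
        ei_l, ej_l = ei.astype(int).tolist(), ej.astype(int).tolist()
        for a, b in zip(ei_l, ej_l):
            nbr[a] |= 1 << b
            nbr[b] |= 1 << a
        pos_of = {(a, b): p for p, (a, b) in enumerate(zip(ei_l, ej_l))}
        tri_cols: list[int] = []
        tri_filt: list[float] = []
        for p, (a, b) in enumerate(zip(ei_l, ej_l)):
            common = nbr[a] & nbr[b] & ~((1 << (b + 1)) - 1)  # only c > b: each tri once
            while common:
                c = common.bit_length() - 1
                common &= ~(1 << c)
                p_ac = pos_of[(a, c)]
                p_bc = pos_of[(b, c)]
                tri_cols.append((1 << p) | (1 << p_ac) | (1 << p_bc))
                tri_filt.append(max(ed[p], ed[p_ac], ed[p_bc]))
        order_t = np.argsort(np.array(tri_filt), kind="stable")

        pivot_t: dict[int, int] = {}  # edge position -> reduced triangle column
        death_of: dict[int, float] = {}
        death_rep: dict[int, int] = {}
        for ti in order_t:
            col = tri_cols[ti]
            while col:
                low = col.bit_length() - 1
                if low not in pivot_t:
                    pivot_t[low] = col
                    death_of[low] = tri_filt[ti]
                    death_rep[low] = col
                    break
                col ^= pivot_t[low]

        for pos, cyc in birth_rep.items():
            birth = float(ed[pos])
            death = death_of.get(pos, max_scale)
            reps[pos] = death_rep.get(pos, cyc)
            h1_deaths[pos] = float(death)
            if death > birth:
                h1_classes.append((birth, float(death), pos))
        h1_classes.sort(key=lambda c: -(c[1] - c[0]))

    h1 = np.array([[b, d] for b, d, _ in h1_classes]) if h1_classes else np.empty((0, 2))
    return RipsResult(
        n_landmarks=n,
        max_scale=float(max_scale),
        edges=edges,
        diagram=PersistenceDiagram({0: h0, 1: h1}),
        h1_classes=h1_classes,
        reps=reps,
        h1_deaths=h1_deaths,
    )


# ---------------------------------------------------------------------------
# Significant classes and the working scale
# ---------------------------------------------------------------------------


@dataclass
class SignificantClasses:
    classes: list[tuple[float, float, int]]  # (birth, death, birth edge position)
    epsilon: float


def significant_classes(
    result: RipsResult,
    rule: str = "ratio",
    gamma: float = 0.5,
    k: int | None = None,
) -> SignificantClasses:
    """Select significant H1 classes and a single working scale epsilon.

    ``rule="ratio"`` keeps classes with persistence >= gamma * max
    persistence; ``rule="top_k"`` keeps the k most persistent.  Epsilon is
    the midpoint of the intersection of the selected (birth, death)
    intervals; if the intervals do not intersect no single scale carries all
    selected classes and an error instructs per-class analysis.
    """
    if not result.h1_classes:
        raise ValueError("no H1 classes in the diagram; nothing to select")
    if rule == "ratio":
        top = result.h1_classes[0][1] - result.h1_classes[0][0]
        selected = [c for c in result.h1_classes if (c[1] - c[0]) >= gamma * top]
    elif rule == "top_k":
        if not k or k < 1:
            raise ValueError("top_k rule requires k >= 1")
        selected = result.h1_classes[:k]
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    lo = max(c[0] for c in selected)
    hi = min(c[1] for c in selected)
    if not lo < hi:
        raise ValueError(
            "selected classes have disjoint life intervals; no single scale exists "
            "-- analyze classes at per-class scales instead"
        )
    return SignificantClasses(classes=selected, epsilon=(lo + hi) / 2.0)


# ---------------------------------------------------------------------------
# H1 basis at the working scale, and walk signatures
# ---------------------------------------------------------------------------


@dataclass
class H1Basis:
    """Cycle-space basis of the epsilon-complex with significance tags.

    Every basis element has a distinct leading edge position, so expressing a
    cycle is a greedy top-bit elimination; the XOR of the tags of the
    eliminating elements yields the H1 coordinates over the significant
    classes.
    """

    epsilon: float
    n_landmarks: int
    edges: np.ndarray  # rows of RipsResult.edges with d <= epsilon (same positions)
    n_edges: int
    basis: dict[int, tuple[int, int]]  # leading edge position -> (cycle, tag bitmask)
    sig_classes: list[tuple[float, float, int]]
    adjacency: sp.csr_matrix  # landmark graph at scale epsilon
    edge_pos: dict[tuple[int, int], int]
    _bfs_cache: dict[int, np.ndarray] = field(default_factory=dict)

    @property
    def n_significant(self) -> int:
        return len(self.sig_classes)

    def shortest_path(self, a: int, b: int) -> list[int]:
        """Shortest (hop-count) landmark path a -> b in the epsilon-complex."""
        if a == b:
            return [a]
        if a not in self._bfs_cache:
            _, pred = breadth_first_order(
                self.adjacency, a, directed=False, return_predecessors=True
            )
            self._bfs_cache[a] = pred
        pred = self._bfs_cache[a]
        if pred[b] < 0 and b != a:
            raise ValueError(
                f"landmark {b} unreachable from {a} in the epsilon-complex "
                f"(epsilon={self.epsilon:.4g}); consider a larger scale"
            )
        path = [b]
        while path[-1] != a:
            path.append(int(pred[path[-1]]))
        path.reverse()
        return path

    def reduce_cycle(self, z: int) -> np.ndarray:
        """H1 coordinates (one bit per significant class) of a mod-2 cycle."""
        tag = 0
        while z:
            low = z.bit_length() - 1
            if low not in self.basis:
                raise ValueError("chain is not a cycle of the epsilon-complex")
            cyc, t = self.basis[low]
            z ^= cyc
            tag ^= t
        bits = np.zeros(self.n_significant, dtype=np.uint8)
        for i in range(self.n_significant):
            bits[i] = (tag >> i) & 1
        return bits


def h1_basis(result: RipsResult, sig: SignificantClasses) -> H1Basis:
    eps = sig.epsilon
    sig_pos = {c[2]: i for i, c in enumerate(sig.classes)}
    keep = result.edges[:, 2] <= eps
    n_edges = int(np.sum(keep))  # edge positions 0..n_edges-1 are exactly those <= eps
    basis: dict[int, tuple[int, int]] = {}
    for pos, rep in result.reps.items():
        if pos >= n_edges:
            continue
        death = result.h1_deaths[pos]
        birth = result.edges[pos, 2]
        if death <= eps:
            tag = 0  # class already dead at epsilon: its stored rep is a boundary
        elif pos in sig_pos:
            tag = 1 << sig_pos[pos]
        else:
            tag = 0  # alive but not significant: quotiented out
        basis[pos] = (rep, tag)
    ei = result.edges[keep, 0].astype(int)
    ej = result.edges[keep, 1].astype(int)
    adj = sp.csr_matrix(
        (np.ones(2 * n_edges, dtype=np.int8), (np.r_[ei, ej], np.r_[ej, ei])),
        shape=(result.n_landmarks, result.n_landmarks),
    )
    edge_pos = {(int(a), int(b)): p for p, (a, b) in enumerate(zip(ei, ej))}
    return H1Basis(
        epsilon=eps,
        n_landmarks=result.n_landmarks,
        edges=result.edges[keep],
        n_edges=n_edges,
        basis=basis,
        sig_classes=list(sig.classes),
        adjacency=adj,
        edge_pos=edge_pos,
    )


@dataclass(frozen=True)
class WalkSignature:
    bits: np.ndarray  # one 0/1 entry per significant H1 class

    def __eq__(self, other) -> bool:  # type: ignore[override]
        return isinstance(other, WalkSignature) and np.array_equal(self.bits, other.bits)


def _itinerary(walk_vertices: np.ndarray, lm: LandmarkSet) -> list[int]:
    lms = lm.assignment[np.asarray(walk_vertices, dtype=np.int64)]
    out: list[int] = []
    for v in lms:
        if not out or out[-1] != v:
            out.append(int(v))
    return out


def _loop_bitset(basis: H1Basis, loop: list[int]) -> int:
    """Mod-2 edge set of a closed landmark loop, filling gaps by shortest paths."""
    z = 0
    for a, b in zip(loop[:-1], loop[1:]):
        if a == b:
            continue
        key = (min(a, b), max(a, b))
        if key in basis.edge_pos:
            z ^= 1 << basis.edge_pos[key]
            continue
        path = basis.shortest_path(a, b)
        for u, v in zip(path[:-1], path[1:]):
            z ^= 1 << basis.edge_pos[(min(u, v), max(u, v))]
    return z


def walk_signature(
    walk: Walk,
    lm: LandmarkSet,
    basis: H1Basis,
    origin_landmark: int,
) -> WalkSignature:
    """Binary H1 coordinates of a walk's closed landmark loop.

    The walk's vertex sequence is mapped to its landmark itinerary (dropping
    consecutive repeats, so duplicating a vertex cannot change the result),
    itinerary gaps and the closure from the terminal landmark back to
    ``origin_landmark`` are filled with shortest paths in the
    epsilon-complex, and the resulting mod-2 cycle is reduced to its
    signature.  The closure path is the same for all walks sharing a
    terminal landmark, so it cancels in pairwise XOR comparisons.
    """
    if len(walk.vertices) == 0:
        raise ValueError("empty walk")
    itin = _itinerary(walk.vertices, lm)
    loop = [origin_landmark] + itin + [origin_landmark]
    z = _loop_bitset(basis, loop)
    return WalkSignature(bits=basis.reduce_cycle(z))


def walk_signatures(
    ws: WalkSet,
    lm: LandmarkSet,
    basis: H1Basis,
    origin_landmark: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Signatures for every walk: (n_walks, n_classes) bit matrix + terminal landmarks."""
    if origin_landmark is None:
        starts = [int(w.vertices[0]) for w in ws.walks]
        origin_landmark = dominant_landmark(lm, starts)
    bits = np.zeros((len(ws), basis.n_significant), dtype=np.uint8)
    terminals = np.zeros(len(ws), dtype=np.int64)
    for i, w in enumerate(ws.walks):
        bits[i] = walk_signature(w, lm, basis, origin_landmark).bits
        terminals[i] = lm.assignment[w.terminal]
    return bits, terminals


# ---------------------------------------------------------------------------
# Walk dendrogram
# ---------------------------------------------------------------------------


@dataclass
class WalkDendrogram:
    """Average-linkage merge tree over walks.

    Distance between walks: Hamming distance of their signatures plus one if
    their terminal landmarks differ, so endpoint selection and topology
    selection compose.
    """

    linkage_matrix: np.ndarray | None  # None for a single-leaf dendrogram
    n_leaves: int

    def leaf_order(self) -> np.ndarray:
        if self.linkage_matrix is None:
            return np.array([0])
        return leaves_list(self.linkage_matrix)

    def cut(self, height: float) -> np.ndarray:
        """Flat cluster labels after cutting all merges above ``height``."""
        if self.linkage_matrix is None:
            return np.array([0])
        merge_heights = self.linkage_matrix[:, 2]
        n_clusters = self.n_leaves - int(np.sum(merge_heights <= height))
        return cut_tree(self.linkage_matrix, n_clusters=n_clusters).ravel()

    def to_newick(self, labels: list[str] | None = None) -> str:
        labels = labels or [f"walk{i}" for i in range(self.n_leaves)]
        if self.linkage_matrix is None:
            return f"{labels[0]};"
        n = self.n_leaves
        heights = {i: 0.0 for i in range(n)}
        nodes = {i: labels[i] for i in range(n)}
        for m, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            la = h - heights[a]
            lb = h - heights[b]
            nodes[n + m] = f"({nodes[a]}:{la:.6g},{nodes[b]}:{lb:.6g})"
            heights[n + m] = h
        return nodes[n + len(self.linkage_matrix) - 1] + ";"


def cluster_walks(
    signatures: np.ndarray,
    terminals: np.ndarray,
) -> WalkDendrogram:
    """Average-linkage dendrogram over walks (deterministic tie-breaks).

    ``signatures`` is the (n_walks, n_classes) bit matrix; ``terminals`` the
    per-walk terminal landmark indices.
    """
    bits = np.asarray(signatures, dtype=np.float64)
    term = np.asarray(terminals)
    if bits.ndim != 2:
        raise ValueError("signatures must be a 2-D bit matrix")
    n = bits.shape[0]
    if n != len(term):
        raise ValueError("one terminal per signature required")
    if n == 1:
        return WalkDendrogram(linkage_matrix=None, n_leaves=1)
    d_bits = pdist(bits, metric="cityblock")
    d_term = pdist(term[:, None], metric="hamming")  # 0/1 per pair
    z = linkage(d_bits + d_term, method="average")
    return WalkDendrogram(linkage_matrix=z, n_leaves=n)
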