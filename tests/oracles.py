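"""Independent oracles used by the tests.

These deliberately avoid the code paths they check: Betti numbers come from
dense GF(2) rank computations over explicitly enumerated simplices, hitting
times from a dense linear solve, absorption probabilities from the
fundamental matrix, and FCS files are re-parsed with a minimal struct-based
reader written separately from the package's parser.
"""

from __future__ import annotations

import struct
from itertools import combinations

import numpy as np
from scipy.spatial.distance import pdist, squareform


# ---------------------------------------------------------------------------
# GF(2) homology of a Rips complex at a fixed scale
# ---------------------------------------------------------------------------


def gf2_rank(mat: np.ndarray) -> int:
    m = (np.asarray(mat, dtype=np.uint8) % 2).copy()
    rank = 0
    rows, cols = m.shape
    for c in range(cols):
        piv = None
        for r in range(rank, rows):
            if m[r, c]:
                piv = r
                break
        if piv is None:
            continue
        m[[rank, piv]] = m[[piv, rank]]
        for r in range(rows):
            if r != rank and m[r, c]:
                m[r] ^= m[rank]
        rank += 1
    return rank


def rips_betti(points: np.ndarray, scale: float) -> tuple[int, int]:
    """(beta0, beta1) of the Vietoris-Rips complex at the given scale."""
    n = len(points)
    dm = squareform(pdist(points))
    edges = [(i, j) for i, j in combinations(range(n), 2) if dm[i, j] <= scale]
    tris = [
        (i, j, k)
        for i, j, k in combinations(range(n), 3)
        if max(dm[i, j], dm[i, k], dm[j, k]) <= scale
    ]
    e_idx = {e: c for c, e in enumerate(edges)}
    d1 = np.zeros((n, len(edges)), dtype=np.uint8)
    for c, (i, j) in enumerate(edges):
        d1[i, c] = d1[j, c] = 1
    d2 = np.zeros((len(edges), len(tris)), dtype=np.uint8)
    for c, (i, j, k) in enumerate(tris):
        for e in ((i, j), (i, k), (j, k)):
            d2[e_idx[e], c] = 1
    r1 = gf2_rank(d1) if edges else 0
    r2 = gf2_rank(d2) if tris else 0
    beta0 = n - r1
    beta1 = len(edges) - r1 - r2
    return beta0, beta1


def cycle_is_boundary(points: np.ndarray, scale: float, cycle_edges: set[tuple[int, int]]) -> bool:
    """Whether a mod-2 edge cycle bounds in the Rips complex at the scale."""
    n = len(points)
    dm = squareform(pdist(points))
    edges = [(i, j) for i, j in combinations(range(n), 2) if dm[i, j] <= scale]
    tris = [
        (i, j, k)
        for i, j, k in combinations(range(n), 3)
        if max(dm[i, j], dm[i, k], dm[j, k]) <= scale
    ]
    e_idx = {e: c for c, e in enumerate(edges)}
    d2 = np.zeros((len(edges), len(tris)), dtype=np.uint8)
    for c, (i, j, k) in enumerate(tris):
        for e in ((i, j), (i, k), (j, k)):
            d2[e_idx[e], c] = 1
    z = np.zeros(len(edges), dtype=np.uint8)
    for e in cycle_edges:
        z[e_idx[tuple(sorted(e))]] = 1
    aug = np.column_stack([d2, z])
    return gf2_rank(aug) == gf2_rank(d2)


# ---------------------------------------------------------------------------
# Markov-chain oracles
# ---------------------------------------------------------------------------


def dense_hitting_times(adj: np.ndarray, absorbing: list[int]) -> np.ndarray:
    """Expected steps to the absorbing set for a uniform-neighbor walk (dense solve)."""
    n = adj.shape[0]
    a = (np.asarray(adj) > 0).astype(float)
    free = [v for v in range(n) if v not in set(absorbing)]
    deg = a.sum(axis=1)
    p = a / deg[:, None]
    q = p[np.ix_(free, free)]
    h = np.zeros(n)
    h[free] = np.linalg.solve(np.eye(len(free)) - q, np.ones(len(free)))
    return h


def absorption_probabilities(
    indptr: np.ndarray, indices: np.ndarray, n: int, start: int
) -> np.ndarray:
    """Exact sink-absorption distribution of a uniform out-edge walk on a DAG."""
    out_deg = np.diff(indptr)
    sinks = np.flatnonzero(out_deg == 0)
    # reverse-topological dynamic program on reach probabilities
    prob = np.zeros(n)
    prob[start] = 1.0
    order = _topological_order(indptr, indices, n)
    absorbed = np.zeros(n)
    for v in order:
        if out_deg[v] == 0:
            absorbed[v] += prob[v]
            continue
        share = prob[v] / out_deg[v]
        for w in indices[indptr[v] : indptr[v + 1]]:
            prob[w] += share
    return absorbed[sinks], sinks


def _topological_order(indptr, indices, n):
    in_deg = np.zeros(n, dtype=np.int64)
    for v in range(n):
        for w in indices[indptr[v] : indptr[v + 1]]:
            in_deg[w] += 1
    stack = [v for v in range(n) if in_deg[v] == 0]
    order = []
    while stack:
        v = stack.pop()
        order.append(v)
        for w in indices[indptr[v] : indptr[v + 1]]:
            in_deg[w] -= 1
            if in_deg[w] == 0:
                stack.append(int(w))
    return order


# ---------------------------------------------------------------------------
# Minimal independent FCS reader
# ---------------------------------------------------------------------------


def minimal_read_fcs(path) -> tuple[list[str], np.ndarray]:
    """Struct-level FCS 3.1 float32 reader, independent of the package parser."""
    blob = open(path, "rb").read()
    assert blob[:6] in (b"FCS3.0", b"FCS3.1")
    tb, te = int(blob[10:18]), int(blob[18:26])
    raw = blob[tb : te + 1]
    delim = raw[0:1].decode()
    parts = raw.decode("latin-1").strip(delim).split(delim)
    kw = dict(zip(parts[::2], parts[1::2]))
    n_par, n_tot = int(kw["$PAR"]), int(kw["$TOT"])
    db = int(blob[26:34]) or int(kw["$BEGINDATA"])
    data = np.frombuffer(blob, dtype="<f4", count=n_par * n_tot, offset=db)
    names = [kw[f"$P{i}N"] for i in range(1, n_par + 1)]
    return names, data.reshape(n_tot, n_par)
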