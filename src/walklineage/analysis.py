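"""Cell-level trajectory analysis: curves, branch points, compositions, and
the probability-binning comparison statistic.

A trajectory bundle is the multiset of cells visited by a selected group of
walks.  Marker-versus-pseudotime curves use equal-occupancy pseudotime bins
(robust to density variation along the trajectory); branch points between
two bundles are localized on a shared equal-width pseudotime grid as the
last bin of sustained member-cell overlap (Jaccard >= tau).

The probability-binning statistic compares two multivariate samples: bins
are built on the reference by recursive quantile splits along the marker of
currently greatest variance until every bin holds an equal share of
reference events (+-1), and the test sample's bin occupancies feed a
chi-square against the reference proportions, standardized as
T = (chi2/K - 1) / sqrt(2/K) so that T ~ 0 with roughly unit variance when
the distributions match and grows with any distributional difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fcs import EventTable
from .graph import PseudotimeField
from .walks import WalkSet

__all__ = [
    "TrajectoryBundle",
    "MarkerCurve",
    "BranchPoint",
    "PBStat",
    "bundle_cells",
    "marker_curve",
    "find_branch_point",
    "subset_distribution",
    "probability_binning_T",
    "permutation_null_T",
]


# ---------------------------------------------------------------------------
# Bundles
# ---------------------------------------------------------------------------


@dataclass
class TrajectoryBundle:
    """Cells visited by a group of walks, with visit counts.

    ``mean_walk_position`` is the per-cell mean of the relative position
    (0 at the walk start, 1 at its terminal) over all visits.
    """

    name: str
    walk_indices: np.ndarray
    cells: np.ndarray  # member cell (vertex) ids, visit count >= m_min
    visit_counts: np.ndarray
    mean_walk_position: np.ndarray

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def multiset_size(self) -> int:
        return int(self.visit_counts.sum())


def bundle_cells(ws: WalkSet, m_min: int = 2, name: str = "bundle") -> TrajectoryBundle:
    """Aggregate a walk set into its member cells.

    A cell is a member if at least ``m_min`` walk visits touch it; the
    default of 2 discards cells grazed by a single stray walk.
    """
    if len(ws) == 0:
        raise ValueError("empty walk set")
    counts: dict[int, int] = {}
    pos_sum: dict[int, float] = {}
    for w in ws.walks:
        L = len(w.vertices)
        denom = max(L - 1, 1)
        for k, v in enumerate(w.vertices):
            v = int(v)
            counts[v] = counts.get(v, 0) + 1
            pos_sum[v] = pos_sum.get(v, 0.0) + k / denom
    cells = np.array(sorted(v for v, c in counts.items() if c >= m_min), dtype=np.int64)
    visits = np.array([counts[v] for v in cells], dtype=np.int64)
    mean_pos = np.array([pos_sum[v] / counts[v] for v in cells])
    return TrajectoryBundle(
        name=name,
        walk_indices=np.arange(len(ws)),
        cells=cells,
        visit_counts=visits,
        mean_walk_position=mean_pos,
    )


# ---------------------------------------------------------------------------
# Marker curves
# ---------------------------------------------------------------------------


@dataclass
class MarkerCurve:
    marker: str
    bin_edges: np.ndarray  # length n_bins + 1, covering [min t, max t] of members
    bin_centers: np.ndarray
    mean: np.ndarray
    dispersion: np.ndarray  # median absolute deviation per bin
    count: np.ndarray
    empty: np.ndarray  # flagged, never interpolated

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center": self.bin_centers,
                "mean": self.mean,
                "mad": self.dispersion,
                "count": self.count,
                "empty": self.empty,
            }
        )


def equal_occupancy_edges(t: np.ndarray, n_bins: int) -> np.ndarray:
    """Quantile bin edges over t; first/last edge pinned to min/max."""
    qs = np.linspace(0.0, 1.0, n_bins + 1)
    edges = np.quantile(t, qs)
    edges[0], edges[-1] = t.min(), t.max()
    return edges


def marker_curve(
    bundle: TrajectoryBundle,
    table: EventTable,
    pt: PseudotimeField,
    marker: str,
    n_bins: int = 50,
    bin_edges: np.ndarray | None = None,
) -> MarkerCurve:
    """Mean marker expression along pseudotime in equal-occupancy bins.

    Member cells enter the statistics once per walk visit, so heavily
    traversed cells weigh more.  Pass ``bin_edges`` to share one binning
    across the markers of a panel figure.
    """
    col = table.marker(marker)
    if bundle.n_cells == 0:
        raise ValueError("bundle has no member cells")
    if n_bins > bundle.multiset_size:
        raise ValueError(
            f"n_bins={n_bins} exceeds the bundle's member multiset size {bundle.multiset_size}"
        )
    cells = np.repeat(bundle.cells, bundle.visit_counts)
    t = pt.t[cells]
    x = col[cells]
    edges = equal_occupancy_edges(t, n_bins) if bin_edges is None else np.asarray(bin_edges)
    which = np.clip(np.searchsorted(edges, t, side="right") - 1, 0, len(edges) - 2)
    n_bins_eff = len(edges) - 1
    mean = np.full(n_bins_eff, np.nan)
    mad = np.full(n_bins_eff, np.nan)
    count = np.zeros(n_bins_eff, dtype=np.int64)
    for b in range(n_bins_eff):
        sel = which == b
        count[b] = sel.sum()
        if count[b]:
            xb = x[sel]
            mean[b] = xb.mean()
            mad[b] = np.median(np.abs(xb - np.median(xb)))
    return MarkerCurve(
        marker=marker,
        bin_edges=edges,
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        mean=mean,
        dispersion=mad,
        count=count,
        empty=count == 0,
    )


# ---------------------------------------------------------------------------
# Branch points
# ---------------------------------------------------------------------------


@dataclass
class BranchPoint:
    """Pseudotime localization of where two bundles stop sharing cells."""

    bin_index: int
    interval: tuple[float, float]
    branch_cells: np.ndarray  # cells shared by both bundles in the branch bin
    overlap_profile: np.ndarray  # per-bin Jaccard overlap in [0, 1]
    bin_edges: np.ndarray
    already_disjoint: bool = False


def find_branch_point(
    a: TrajectoryBundle,
    b: TrajectoryBundle,
    pt: PseudotimeField,
    n_bins: int = 50,
    tau: float = 0.5,
) -> BranchPoint:
    """Last pseudotime bin where the two bundles still overlap (Jaccard >= tau).

    Bins are equal-width over the union of both bundles' member pseudotimes
    so the two share one grid; the construction is symmetric in (a, b).
    Bundles with no overlapping bin at all yield an explicit
    "already disjoint" result at the first bin rather than an error.
    """
    t_all = pt.t[np.concatenate([a.cells, b.cells])]
    lo, hi = float(t_all.min()), float(t_all.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    set_a, set_b = set(a.cells.tolist()), set(b.cells.tolist())

    def bin_of(cells: np.ndarray) -> np.ndarray:
        return np.clip(np.searchsorted(edges, pt.t[cells], side="right") - 1, 0, n_bins - 1)

    bins_a, bins_b = bin_of(a.cells), bin_of(b.cells)
    profile = np.zeros(n_bins)
    shared_per_bin: list[np.ndarray] = []
    for k in range(n_bins):
        ca = set(a.cells[bins_a == k].tolist())
        cb = set(b.cells[bins_b == k].tolist())
        union = ca | cb
        inter = ca & cb
        profile[k] = len(inter) / len(union) if union else 0.0
        shared_per_bin.append(np.array(sorted(inter), dtype=np.int64))

    above = np.flatnonzero(profile >= tau)
    if above.size == 0:
        return BranchPoint(
            bin_index=0,
            interval=(float(edges[0]), float(edges[1])),
            branch_cells=np.array([], dtype=np.int64),
            overlap_profile=profile,
            bin_edges=edges,
            already_disjoint=True,
        )
    k = int(above[-1])
    return BranchPoint(
        bin_index=k,
        interval=(float(edges[k]), float(edges[k + 1])),
        branch_cells=shared_per_bin[k],
        overlap_profile=profile,
        bin_edges=edges,
    )


# ---------------------------------------------------------------------------
# Subset distributions
# ---------------------------------------------------------------------------


def subset_distribution(tables: list[EventTable]) -> pd.DataFrame:
    """Relative gate-label frequencies per sample (rows sum to 1)."""
    frames = []
    for t in tables:
        if t.gate_label is None:
            raise ValueError("subset_distribution requires gate labels on every table")
        frames.append(pd.DataFrame({"sample_id": t.sample_id, "label": t.gate_label}))
    df = pd.concat(frames, ignore_index=True)
    counts = df.groupby(["sample_id", "label"], sort=True).size().unstack(fill_value=0)
    freq = counts.div(counts.sum(axis=1), axis=0)
    return freq


# ---------------------------------------------------------------------------
# Probability binning
# ---------------------------------------------------------------------------


@dataclass
class PBStat:
    T: float
    n_bins: int
    reference_counts: np.ndarray
    test_counts: np.ndarray
    chi2: float


@dataclass
class _SplitNode:
    marker: int | None = None
    threshold: float = 0.0
    left: "_SplitNode | None" = None
    right: "_SplitNode | None" = None
    leaf_id: int = -1


def _build_bins(x: np.ndarray, idx: np.ndarray, m: int, leaves: list[np.ndarray]) -> _SplitNode:
    """Recursive quantile split: node holding m final bins splits m//2 : m - m//2.

    The split marker is the one with greatest variance among the node's
    reference events (the classic probability-binning construction); the
    quantile generalizes the median so that any bin count gives equal
    occupancies +-1.
    """
    node = _SplitNode()
    if m == 1:
        node.leaf_id = len(leaves)
        leaves.append(idx)
        return node
    sub = x[idx]
    node.marker = int(np.argmax(sub.var(axis=0)))
    vals = sub[:, node.marker]
    m_left = m // 2
    n_left = int(round(len(idx) * m_left / m))
    order = np.argsort(vals, kind="stable")
    left_idx = idx[order[:n_left]]
    right_idx = idx[order[n_left:]]
    v_sorted = vals[order]
    node.threshold = float(0.5 * (v_sorted[n_left - 1] + v_sorted[n_left]))
    node.left = _build_bins(x, left_idx, m_left, leaves)
    node.right = _build_bins(x, right_idx, m - m_left, leaves)
    return node


def _assign_bins(node: _SplitNode, x: np.ndarray, idx: np.ndarray, out: np.ndarray) -> None:
    if node.leaf_id >= 0:
        out[idx] = node.leaf_id
        return
    vals = x[idx, node.marker]
    left = vals <= node.threshold
    _assign_bins(node.left, x, idx[left], out)
    _assign_bins(node.right, x, idx[~left], out)


def probability_binning_T(
    reference: EventTable | np.ndarray,
    test: EventTable | np.ndarray,
    markers: list[str] | None = None,
    n_bins: int = 100,
) -> PBStat:
    """Standardized chi-square over probability bins built on the reference.

    T ~ 0 for matching distributions; T <= 0 can occur (an identical copy of
    the reference under-disperses the chi-square) and is reported as-is.
    """
    def to_matrix(t):
        if isinstance(t, EventTable):
            cols = markers or t.marker_names
            return np.column_stack([t.marker(m) for m in cols])
        return np.asarray(t, dtype=np.float64)

    ref = to_matrix(reference)
    tst = to_matrix(test)
    if ref.shape[1] != tst.shape[1]:
        raise ValueError("reference and test must share the marker set")
    if ref.shape[0] < 2 * n_bins:
        raise ValueError(
            f"reference has {ref.shape[0]} events; probability binning with "
            f"{n_bins} bins needs at least {2 * n_bins}"
        )
    leaves: list[np.ndarray] = []
    tree = _build_bins(ref, np.arange(ref.shape[0]), n_bins, leaves)
    ref_counts = np.array([len(l) for l in leaves], dtype=np.int64)
    assert ref_counts.max() - ref_counts.min() <= 1

    test_bins = np.empty(tst.shape[0], dtype=np.int64)
    _assign_bins(tree, tst, np.arange(tst.shape[0]), test_bins)
    test_counts = np.bincount(test_bins, minlength=n_bins)

    p = ref_counts / ref_counts.sum()
    expected = tst.shape[0] * p
    # reference proportions are estimates, which inflates the raw chi-square
    # by (1 + n_test/n_ref); correcting keeps E[chi2] ~ K - 1 under the null
    correction = 1.0 + tst.shape[0] / ref.shape[0]
    chi2 = float(np.sum((test_counts - expected) ** 2 / expected) / correction)
    t_val = (chi2 / n_bins - 1.0) / np.sqrt(2.0 / n_bins)
    return PBStat(
        T=float(t_val),
        n_bins=n_bins,
        reference_counts=ref_counts,
        test_counts=test_counts,
        chi2=chi2,
    )


def permutation_null_T(
    reference: np.ndarray,
    test: np.ndarray,
    n_bins: int = 100,
    n_perm: int = 200,
    seed: int = 0,
) -> np.ndarray:
    """Null distribution of T under random relabeling of the pooled events."""
    pool = np.vstack([reference, test])
    n_ref = reference.shape[0]
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(pool.shape[0])
        r, t = pool[perm[:n_ref]], pool[perm[n_ref:]]
        out[i] = probability_binning_T(r, t, n_bins=n_bins).T
    return out
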