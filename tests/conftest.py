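"""Shared fixtures: tiny graphs and synthetic datasets, built fresh per session."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp

import walklineage as wl
from walklineage.graph import KnnGraph


def graph_from_edges(n: int, edges: list[tuple[int, int]]) -> KnnGraph:
    """A KnnGraph wrapper around an explicit undirected edge list (unit weights)."""
    rows, cols = [], []
    for u, v in edges:
        rows += [u, v]
        cols += [v, u]
    adj = sp.csr_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n))
    return KnnGraph(
        n_vertices=n,
        k=2,
        metric="euclidean",
        neighbor_indices=np.zeros((n, 1), dtype=np.int64),
        neighbor_distances=np.zeros((n, 1)),
        adjacency=adj,
    )


@pytest.fixture(scope="session")
def path_graph() -> KnnGraph:
    """The 4-vertex path 0-1-2-3."""
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])


@pytest.fixture(scope="session")
def y_graph() -> KnnGraph:
    """A stem 0-1-2 splitting into arms 2-3-4 and 2-5-6."""
    return graph_from_edges(7, [(0, 1), (1, 2), (2, 3), (3, 4), (2, 5), (5, 6)])


@pytest.fixture(scope="session")
def loop_dataset() -> wl.SyntheticDataset:
    """Annulus-shaped two-route dataset (one H1 class), 3000 cells."""
    topo, kin = wl.preset_loop(n_markers=6)
    return wl.generate(topo, kin, n_cells=3000, noise_sd=0.08, seed=21)


@pytest.fixture(scope="session")
def bcell_dataset() -> wl.SyntheticDataset:
    """Small B-lymphopoiesis-like dataset for module-level tests."""
    topo, kin = wl.preset_bcell_like(30)
    return wl.generate(topo, kin, n_cells=6000, noise_sd=0.1, seed=13)


@pytest.fixture(scope="session")
def bcell_graph(bcell_dataset):
    return wl.build_knn_graph(bcell_dataset.table, k=15)


@pytest.fixture(scope="session")
def bcell_pt(bcell_dataset, bcell_graph):
    origin = np.flatnonzero(bcell_dataset.table.gate_label == "stem")
    return wl.compute_pseudotime(bcell_graph, origin)
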