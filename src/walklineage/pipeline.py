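"""End-to-end orchestration: one config in, a run directory of artifacts out.

Stages (transform -> graph -> pseudotime -> walks -> topology -> embedding
-> trajectory reports -> enhanced FCS) are isolated: each consumes only
artifacts persisted by earlier stages, so a run can be resumed or a single
stage re-executed.  All randomness derives from the explicit seeds in the
config; re-running with an identical config reproduces every numeric
artifact bit for bit at float32.

A frozen run can then be reused: :func:`map_new_sample` embeds a newly
acquired sample with the stored model, assigns each new cell to reference
pseudotime and trajectories by nearest reference neighbors, and emits a
subset-distribution comparison against the reference.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from . import analysis, embedding as emb, fcs, graph as gr, synthetic, topology as topo, walks as wk

__all__ = ["RunConfig", "run_pipeline", "map_new_sample", "save_events_h5", "load_events_h5"]

logger = logging.getLogger(__name__)

STAGES = (
    "transform",
    "graph",
    "pseudotime",
    "walks",
    "topology",
    "embedding",
    "trajectory",
    "export",
)


@dataclass
class RunConfig:
    """Everything a run needs; all seeds explicit (no wall-clock seeding)."""

    fcs_files: list[str]
    panel: str
    gates: str | None
    origin_label: str
    out_dir: str
    endpoint_labels: list[str] = field(default_factory=list)
    endpoint_boxes: list[list[float]] = field(default_factory=list)  # [x0, x1, y0, y1] in embedding coords
    keep_labels: list[str] | None = None
    cofactor: float = 5.0
    k: int = 30
    n_walks: int = 5000
    min_walks: int = 10
    hop_radius: int = 2
    landmarks: int = 500
    gamma: float = 0.5
    max_scale: float | None = None
    curve_markers: list[str] = field(default_factory=list)
    n_bins: int = 50
    tau: float = 0.5
    m_min: int = 2
    embedding: dict = field(default_factory=dict)
    seed: int = 7

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def stage_seed(self, stage: str) -> int:
        # stable per-stage derivation, kept below 2**31
        h = hashlib.sha256(f"{self.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31)


# ---------------------------------------------------------------------------
# Event-table persistence (HDF5)
# ---------------------------------------------------------------------------


def save_events_h5(path: str | Path, table: fcs.EventTable) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=table.values.astype(np.float32))
        f.create_dataset("marker_names", data=np.array(table.marker_names, dtype="S"))
        f.create_dataset("sample_id", data=np.array([str(s) for s in table.sample_id], dtype="S"))
        if table.gate_label is not None:
            f.create_dataset(
                "gate_label", data=np.array([str(g) for g in table.gate_label], dtype="S")
            )
        f.attrs["transform_state"] = table.transform_state


def load_events_h5(path: str | Path) -> fcs.EventTable:
    with h5py.File(path, "r") as f:
        gate = None
        if "gate_label" in f:
            gate = np.array([g.decode() for g in f["gate_label"][()]], dtype=object)
        return fcs.EventTable(
            values=f["values"][()].astype(np.float64),
            marker_names=[m.decode() for m in f["marker_names"][()]],
            sample_id=np.array([s.decode() for s in f["sample_id"][()]], dtype=object),
            gate_label=gate,
            transform_state=str(f.attrs["transform_state"]),
        )


def _log_event(run_dir: Path, **payload) -> None:
    payload.setdefault("ts", time.time())
    with open(run_dir / "log.jsonl", "a") as fh:
        fh.write(json.dumps(payload, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def _stage_transform(cfg: RunConfig, run: Path) -> None:
    panel = fcs.read_panel_csv(cfg.panel)
    gates = fcs.read_gate_csv(cfg.gates) if cfg.gates else None
    tables = []
    for path in cfg.fcs_files:
        t = fcs.read_fcs(path, panel)
        t = fcs.arcsinh_transform(t, cfg.cofactor)
        if gates is not None:
            t = fcs.apply_gate_labels(t, gates)
        tables.append(t)
    table = fcs.concatenate(tables, cfg.keep_labels)
    save_events_h5(run / "events.h5", table)


def _stage_graph(cfg: RunConfig, run: Path) -> None:
    table = load_events_h5(run / "events.h5")
    g = gr.build_knn_graph(table, k=cfg.k)
    with h5py.File(run / "graph.h5", "w") as f:
        f.create_dataset("indptr", data=g.adjacency.indptr)
        f.create_dataset("indices", data=g.adjacency.indices)
        f.create_dataset("data", data=g.adjacency.data)
        f.create_dataset("knn_indices", data=g.neighbor_indices)
        f.create_dataset("knn_distances", data=g.neighbor_distances)
        f.attrs["n_vertices"] = g.n_vertices
        f.attrs["k"] = g.k
        f.attrs["metric"] = g.metric
        f.attrs["n_repair_edges"] = g.n_repair_edges


def _load_graph(run: Path) -> gr.KnnGraph:
    import scipy.sparse as sp

    with h5py.File(run / "graph.h5", "r") as f:
        n = int(f.attrs["n_vertices"])
        adj = sp.csr_matrix((f["data"][()], f["indices"][()], f["indptr"][()]), shape=(n, n))
        return gr.KnnGraph(
            n_vertices=n,
            k=int(f.attrs["k"]),
            metric=str(f.attrs["metric"]),
            neighbor_indices=f["knn_indices"][()],
            neighbor_distances=f["knn_distances"][()],
            adjacency=adj,
            n_repair_edges=int(f.attrs["n_repair_edges"]),
        )


def _label_indices(table: fcs.EventTable, labels: list[str] | str) -> np.ndarray:
    if table.gate_label is None:
        raise ValueError("gate labels are required to select labeled vertex sets")
    wanted = {labels} if isinstance(labels, str) else set(labels)
    missing = wanted - set(np.unique(table.gate_label.astype(str)))
    if missing:
        raise ValueError(f"label(s) {sorted(missing)} not present in the gate labels")
    return np.flatnonzero(np.isin(table.gate_label.astype(str), list(wanted)))


def _endpoint_indices(cfg: RunConfig, table: fcs.EventTable, run: Path) -> np.ndarray:
    idx: list[np.ndarray] = []
    if cfg.endpoint_labels:
        idx.append(_label_indices(table, cfg.endpoint_labels))
    if cfg.endpoint_boxes:
        coords_path = run / "embedding.h5"
        if not coords_path.exists():
            raise ValueError(
                "endpoint_boxes require embedding coordinates; run the embedding "
                "stage before pseudotime or use endpoint_labels"
            )
        with h5py.File(coords_path, "r") as f:
            xy = f["coords"][()]
        for x0, x1, y0, y1 in cfg.endpoint_boxes:
            idx.append(
                np.flatnonzero(
                    (xy[:, 0] >= x0) & (xy[:, 0] <= x1) & (xy[:, 1] >= y0) & (xy[:, 1] <= y1)
                )
            )
    if not idx:
        return np.array([], dtype=np.int64)
    return np.unique(np.concatenate(idx))


def _stage_pseudotime(cfg: RunConfig, run: Path) -> None:
    table = load_events_h5(run / "events.h5")
    g = _load_graph(run)
    origin = _label_indices(table, cfg.origin_label)
    endpoints = _endpoint_indices(cfg, table, run)
    endpoints = np.setdiff1d(endpoints, origin)
    if endpoints.size:
        pt = gr.recompute_pseudotime_with_endpoints(g, origin, endpoints)
    else:
        pt = gr.compute_pseudotime(g, origin)
    with h5py.File(run / "pseudotime.h5", "w") as f:
        f.create_dataset("t", data=pt.t)
        f.create_dataset("origin", data=pt.origin)
        f.create_dataset("endpoints", data=pt.endpoints if pt.endpoints is not None else np.array([], dtype=np.int64))
        f.attrs["mode"] = pt.mode


def _load_pseudotime(run: Path) -> gr.PseudotimeField:
    with h5py.File(run / "pseudotime.h5", "r") as f:
        eps = f["endpoints"][()]
        return gr.PseudotimeField(
            t=f["t"][()],
            mode=str(f.attrs["mode"]),
            origin=f["origin"][()],
            endpoints=eps if eps.size else None,
        )


def _stage_walks(cfg: RunConfig, run: Path) -> None:
    g = _load_graph(run)
    pt = _load_pseudotime(run)
    og = gr.orient_edges(g, pt)
    ws = wk.simulate_walks(og, pt.origin, n_walks=cfg.n_walks, seed=cfg.stage_seed("walks"))
    groups = wk.detect_endpoint_groups(ws, g, min_walks=cfg.min_walks, hop_radius=cfg.hop_radius)
    flat = np.concatenate([w.vertices for w in ws.walks])
    offsets = np.cumsum([0] + [len(w.vertices) for w in ws.walks])
    with h5py.File(run / "walks.h5", "w") as f:
        f.create_dataset("flat", data=flat)
        f.create_dataset("offsets", data=offsets)
        f.attrs["seed"] = ws.seed
        f.attrs["n_requested"] = ws.n_requested
    (run / "endpoint_groups.json").write_text(
        json.dumps(
            [
                {
                    "name": g_.name,
                    "sinks": sorted(g_.sinks),
                    "member_walks": g_.member_walks.tolist(),
                }
                for g_ in groups
            ],
            indent=2,
        )
    )


def _load_walks(run: Path) -> tuple[wk.WalkSet, list[wk.EndpointGroup]]:
    with h5py.File(run / "walks.h5", "r") as f:
        flat = f["flat"][()]
        offsets = f["offsets"][()]
        seed = int(f.attrs["seed"])
        n_req = int(f.attrs["n_requested"])
    walks = [
        wk.Walk(flat[offsets[i] : offsets[i + 1]]) for i in range(len(offsets) - 1)
    ]
    ws = wk.WalkSet(walks=walks, seed=seed, n_requested=n_req)
    raw = json.loads((run / "endpoint_groups.json").read_text())
    groups = [
        wk.EndpointGroup(
            name=g_["name"],
            sinks=frozenset(g_["sinks"]),
            member_walks=np.array(g_["member_walks"], dtype=np.int64),
        )
        for g_ in raw
    ]
    return ws, groups


def _stage_topology(cfg: RunConfig, run: Path) -> None:
    table = load_events_h5(run / "events.h5")
    ws, _ = _load_walks(run)
    lm = topo.select_landmarks(table, count=min(cfg.landmarks, table.n_events), seed=cfg.stage_seed("landmarks"))
    from scipy.spatial.distance import pdist

    dists = pdist(lm.coordinates)
    max_scale = cfg.max_scale if cfg.max_scale is not None else float(np.quantile(dists, 0.30))
    result = topo.compute_persistence(lm, max_scale=max_scale, max_dim=1)
    pd.DataFrame(
        [(dim, b, d) for dim, pairs in result.diagram.pairs.items() for b, d in pairs],
        columns=["dim", "birth", "death"],
    ).to_csv(run / "persistence_diagram.csv", index=False)

    pt = _load_pseudotime(run)
    origin_lm = topo.dominant_landmark(lm, pt.origin)
    try:
        sig = topo.significant_classes(result, rule="ratio", gamma=cfg.gamma)
        basis = topo.h1_basis(result, sig)
        bits, terminals = topo.walk_signatures(ws, lm, basis, origin_lm)
        n_sig = basis.n_significant
    except ValueError as exc:
        _log_event(run, stage="topology", note=f"no usable H1 classes ({exc}); clustering by terminal only")
        bits = np.zeros((len(ws), 1), dtype=np.uint8)
        terminals = np.array([lm.assignment[w.terminal] for w in ws.walks])
        n_sig = 0
    dend = topo.cluster_walks(bits, terminals)
    (run / "walk_dendrogram.nwk").write_text(dend.to_newick())
    with h5py.File(run / "topology.h5", "w") as f:
        f.create_dataset("signatures", data=bits)
        f.create_dataset("terminal_landmarks", data=terminals)
        f.create_dataset("landmark_indices", data=lm.indices)
        f.create_dataset("landmark_assignment", data=lm.assignment)
        f.attrs["n_significant"] = n_sig
        f.attrs["max_scale"] = max_scale
        f.attrs["origin_landmark"] = origin_lm


def _stage_embedding(cfg: RunConfig, run: Path) -> None:
    table = load_events_h5(run / "events.h5")
    e_cfg = emb.EmbeddingConfig(**cfg.embedding) if cfg.embedding else emb.EmbeddingConfig()
    model = emb.train_embedding(table, e_cfg, seed=cfg.stage_seed("embedding"))
    emb.save_model(model, run / "embedding_model.npz")
    coords = emb.embed(model, table)
    with h5py.File(run / "embedding.h5", "w") as f:
        f.create_dataset("coords", data=coords.astype(np.float32))
    _scatter_plot(run, coords, table)


def _scatter_plot(run: Path, coords: np.ndarray, table: fcs.EventTable) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    if table.gate_label is not None:
        for lbl in pd.unique(table.gate_label):
            m = table.gate_label == lbl
            ax.scatter(coords[m, 0], coords[m, 1], s=2, alpha=0.5, label=str(lbl))
        ax.legend(fontsize=6, markerscale=3, loc="best")
    else:
        ax.scatter(coords[:, 0], coords[:, 1], s=2, alpha=0.5)
    ax.set_xlabel("vae1")
    ax.set_ylabel("vae2")
    fig.tight_layout()
    fig.savefig(run / "embedding_scatter.png", dpi=120)
    plt.close(fig)


def _stage_trajectory(cfg: RunConfig, run: Path) -> None:
    table = load_events_h5(run / "events.h5")
    pt = _load_pseudotime(run)
    ws, groups = _load_walks(run)
    markers = cfg.curve_markers or table.marker_names[: min(3, table.n_markers)]
    bundles = {}
    curve_rows = []
    for group in groups:
        sel = wk.select_walks(ws, group)
        bundle = analysis.bundle_cells(sel, m_min=cfg.m_min, name=group.name)
        bundles[group.name] = bundle
        edges = analysis.equal_occupancy_edges(
            pt.t[np.repeat(bundle.cells, bundle.visit_counts)],
            min(cfg.n_bins, max(2, bundle.multiset_size // 2)),
        )
        for marker in markers:
            curve = analysis.marker_curve(bundle, table, pt, marker, bin_edges=edges)
            df = curve.to_frame()
            df.insert(0, "marker", marker)
            df.insert(0, "bundle", group.name)
            curve_rows.append(df)
    if curve_rows:
        pd.concat(curve_rows, ignore_index=True).to_csv(run / "marker_curves.csv", index=False)

    branch_rows = []
    names = list(bundles)
    for i in range(len(names)):
        for j in range(i + 1, min(i + 2, len(names))):  # adjacent pairs keep output compact
            bp = analysis.find_branch_point(
                bundles[names[i]], bundles[names[j]], pt, n_bins=cfg.n_bins, tau=cfg.tau
            )
            branch_rows.append(
                {
                    "bundle_a": names[i],
                    "bundle_b": names[j],
                    "bin_index": bp.bin_index,
                    "t_lo": bp.interval[0],
                    "t_hi": bp.interval[1],
                    "n_branch_cells": len(bp.branch_cells),
                    "already_disjoint": bp.already_disjoint,
                }
            )
    if branch_rows:
        pd.DataFrame(branch_rows).to_csv(run / "branch_points.csv", index=False)

    memberships = {}
    for name, bundle in bundles.items():
        ind = np.zeros(table.n_events)
        ind[bundle.cells] = 1.0
        memberships[name] = ind
    np.savez(run / "bundles.npz", **{n: b.cells for n, b in bundles.items()})
    with open(run / "memberships.json", "w") as fh:
        json.dump({n: int(m.sum()) for n, m in memberships.items()}, fh)


def _stage_export(cfg: RunConfig, run: Path) -> None:
    table = load_events_h5(run / "events.h5")
    pt = _load_pseudotime(run)
    with h5py.File(run / "embedding.h5", "r") as f:
        coords = f["coords"][()].astype(np.float64)
    bundles = np.load(run / "bundles.npz")
    memberships = {}
    for name in bundles.files:
        ind = np.zeros(table.n_events)
        ind[bundles[name]] = 1.0
        memberships[name] = ind
    derived = fcs.DerivedChannels.assemble(
        table.n_events,
        embedding=coords,
        pseudotime=np.maximum(pt.t, 0.0),
        memberships=memberships,
    )
    fcs.export_enhanced_fcs(table, derived, run / "enhanced.fcs")


_STAGE_FUNCS = {
    "transform": _stage_transform,
    "graph": _stage_graph,
    "pseudotime": _stage_pseudotime,
    "walks": _stage_walks,
    "topology": _stage_topology,
    "embedding": _stage_embedding,
    "trajectory": _stage_trajectory,
    "export": _stage_export,
}


def run_pipeline(config: RunConfig, stages: list[str] | None = None) -> Path:
    """Execute the pipeline stages in order; returns the run directory.

    A stage error aborts the run with the stage name; artifacts persisted by
    completed stages remain in place, together with the provenance log.
    """
    run = Path(config.out_dir)
    run.mkdir(parents=True, exist_ok=True)
    (run / "config.json").write_text(config.to_json())
    cfg_hash = hashlib.sha256(config.to_json().encode()).hexdigest()
    provenance = {
        "config_sha256": cfg_hash,
        "seed": config.seed,
        "stage_seeds": {s: config.stage_seed(s) for s in STAGES},
        "versions": _versions(),
    }
    (run / "provenance.json").write_text(json.dumps(provenance, indent=2, sort_keys=True))
    for stage in stages or STAGES:
        t0 = time.time()
        try:
            _STAGE_FUNCS[stage](config, run)
        except Exception as exc:
            _log_event(run, stage=stage, status="error", error=str(exc))
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        _log_event(run, stage=stage, status="ok", seconds=round(time.time() - t0, 3))
    return run


def _versions() -> dict[str, str]:
    import scipy
    import sklearn

    from . import __version__

    return {
        "walklineage": __version__,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "sklearn": sklearn.__version__,
    }


# ---------------------------------------------------------------------------
# Mapping new samples onto a frozen run
# ---------------------------------------------------------------------------


def map_new_sample(
    run_dir: str | Path,
    sample: str | Path | fcs.EventTable,
    k_assign: int = 5,
    sample_id: str | None = None,
) -> dict:
    """Embed a new sample with the frozen model and compare it to the reference.

    Cells are placed in the stored 2D projection, then assigned a reference
    gate label, pseudotime and trajectory memberships by majority /
    average over their ``k_assign`` nearest reference cells in marker space.
    Returns a report dict with the comparison table and writes
    ``mapped_<sample>.csv`` plus an overlay plot into the run directory.
    """
    from sklearn.neighbors import NearestNeighbors

    run = Path(run_dir)
    cfg = RunConfig.from_json(run / "config.json")
    model = emb.load_model(run / "embedding_model.npz")
    reference = load_events_h5(run / "events.h5")
    pt = _load_pseudotime(run)

    if isinstance(sample, fcs.EventTable):
        table = sample
    else:
        panel = fcs.read_panel_csv(cfg.panel)
        table = fcs.read_fcs(sample, panel, sample_id=sample_id)
        table = fcs.arcsinh_transform(table, cfg.cofactor)
    coords = emb.embed(model, table)

    cols = [table.marker_index(m) for m in reference.marker_names]
    nn = NearestNeighbors(n_neighbors=k_assign).fit(reference.values)
    _, nbr = nn.kneighbors(table.values[:, cols])

    ref_labels = reference.gate_label.astype(str)
    assigned = np.empty(table.n_events, dtype=object)
    for i in range(table.n_events):
        lbls, cnt = np.unique(ref_labels[nbr[i]], return_counts=True)
        assigned[i] = lbls[np.argmax(cnt)]
    mapped_pt = pt.t[nbr].mean(axis=1)

    bundles = np.load(run / "bundles.npz")
    member = {}
    for name in bundles.files:
        ind = np.zeros(reference.n_events)
        ind[bundles[name]] = 1.0
        member[name] = (ind[nbr].mean(axis=1) > 0.5).astype(float)

    sid = str(table.sample_id[0])
    if sid in set(reference.sample_id.astype(str)):
        sid = f"{sid}_mapped"
    mapped_table = fcs.EventTable(
        values=table.values,
        marker_names=table.marker_names,
        sample_id=np.repeat(np.array([sid], dtype=object), table.n_events),
        gate_label=assigned,
        transform_state=table.transform_state,
    )
    dist = analysis.subset_distribution([reference, mapped_table])
    out_csv = run / f"mapped_{sid}_distribution.csv"
    dist.to_csv(out_csv)

    _overlay_plot(run, coords, sid)
    return {
        "coords": coords,
        "assigned_label": assigned,
        "pseudotime": mapped_pt,
        "memberships": member,
        "distribution": dist,
        "distribution_csv": str(out_csv),
    }


def _overlay_plot(run: Path, coords: np.ndarray, sid: str) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    with h5py.File(run / "embedding.h5", "r") as f:
        ref = f["coords"][()]
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(ref[:, 0], ref[:, 1], s=2, alpha=0.2, color="grey", label="reference")
    ax.scatter(coords[:, 0], coords[:, 1], s=2, alpha=0.5, color="crimson", label=sid)
    ax.legend(markerscale=4)
    fig.tight_layout()
    fig.savefig(run / f"mapped_{sid}_overlay.png", dpi=120)
    plt.close(fig)
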