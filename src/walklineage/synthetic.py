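"""Synthetic branching single-cell datasets with known ground truth.

The generator emulates what a developmental hierarchy looks like through a
~30-marker mass-cytometry panel after variance stabilization: cells are drawn
along root-to-leaf paths of a staged topology, each marker follows smooth
kinetic primitives of latent time (logistic on/off switches, Gaussian bumps,
circular arcs for loop topologies), and i.i.d. Gaussian noise is added on the
transformed scale.  Ground truth (path, stage, latent time, loop side) is
recorded per event, which makes every downstream inference step testable.

Two presets are provided: :func:`preset_bcell_like`, a B-lymphopoiesis-like
tree (stem -> pro-B -> pre-BI -> pre-BII -> immature -> transitional ->
kappa/lambda naive split -> effector/memory split, plus a rare plasma-cell
tip reachable only through a long low-density corridor), and
:func:`preset_loop`, two parallel routes between the same start and end
arranged as an annulus, creating exactly one first-homology class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path as FsPath
from typing import Sequence

import numpy as np
import pandas as pd

from .fcs import EventTable, write_fcs

__all__ = [
    "Kinetic",
    "LineagePath",
    "TopologySpec",
    "KineticsSpec",
    "SyntheticDataset",
    "generate",
    "preset_bcell_like",
    "preset_loop",
    "export_dataset",
]


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Kinetic:
    """A marker kinetic primitive as a function of latent time t in [0, 1].

    kinds: ``logistic_up`` (amplitude * sigmoid((t-center)/width)),
    ``logistic_down`` (mirror image), ``bump`` (Gaussian, center/width),
    ``constant`` (amplitude), and the arc primitives ``arc_cos`` /
    ``arc_sin`` / ``arc_sin_neg`` used to trace an annulus
    (amplitude * cos/±sin of pi*(1-t)).
    """

    kind: str
    center: float = 0.5
    width: float = 0.05
    amplitude: float = 1.0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("kinetic amplitudes must be nonnegative")
        if self.kind not in (
            "logistic_up",
            "logistic_down",
            "bump",
            "constant",
            "arc_cos",
            "arc_sin",
            "arc_sin_neg",
        ):
            raise ValueError(f"unknown kinetic kind {self.kind!r}")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=np.float64)
        if self.kind == "constant":
            return np.full_like(t, self.amplitude)
        if self.kind == "logistic_up":
            return self.amplitude / (1.0 + np.exp(-(t - self.center) / self.width))
        if self.kind == "logistic_down":
            return self.amplitude / (1.0 + np.exp((t - self.center) / self.width))
        if self.kind == "bump":
            return self.amplitude * np.exp(-0.5 * ((t - self.center) / self.width) ** 2)
        theta = np.pi * (1.0 - t)
        if self.kind == "arc_cos":
            return self.amplitude * np.cos(theta)
        if self.kind == "arc_sin":
            return self.amplitude * np.sin(theta)
        return -self.amplitude * np.sin(theta)


@dataclass(frozen=True)
class LineagePath:
    """One root-to-leaf path: ordered stages with latent-time intervals."""

    name: str
    weight: float
    stages: tuple[tuple[str, float, float], ...]
    side_label: str | None = None

    def validate(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"path {self.name!r}: weight must be positive")
        if not self.stages:
            raise ValueError(f"path {self.name!r}: no stages")
        t_prev = 0.0
        for stage, t0, t1 in self.stages:
            if not np.isclose(t0, t_prev):
                raise ValueError(
                    f"path {self.name!r}: stage {stage!r} starts at {t0}, expected {t_prev} "
                    "(intervals must tile [0, 1] monotonically)"
                )
            if t1 <= t0:
                raise ValueError(f"path {self.name!r}: stage {stage!r} has empty interval")
            t_prev = t1
        if not np.isclose(t_prev, 1.0):
            raise ValueError(f"path {self.name!r}: stages cover [0, {t_prev}], must cover [0, 1]")

    def stage_at(self, t: np.ndarray) -> np.ndarray:
        edges = np.array([s[2] for s in self.stages])
        idx = np.minimum(np.searchsorted(edges, t, side="right"), len(self.stages) - 1)
        names = np.array([s[0] for s in self.stages], dtype=object)
        return names[idx]

    @property
    def leaf(self) -> str:
        return self.stages[-1][0]


@dataclass(frozen=True)
class TopologySpec:
    """A branching (optionally looping) topology given as weighted paths.

    All paths must share the same root stage (single origin); a loop is two
    paths sharing their first and last stage but routed through different
    intermediate stages (recorded via ``side_label``).
    """

    paths: tuple[LineagePath, ...]

    def __post_init__(self) -> None:
        if not self.paths:
            raise ValueError("topology has no paths")
        roots = {p.stages[0][0] for p in self.paths}
        if len(roots) != 1:
            raise ValueError(f"topology must have exactly one root stage, found {sorted(roots)}")
        for p in self.paths:
            p.validate()
        total = sum(p.weight for p in self.paths)
        if not np.isclose(total, 1.0):
            raise ValueError(f"path weights must sum to 1, got {total}")

    @property
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.paths:
            for s, _, _ in p.stages:
                seen.setdefault(s)
        return list(seen)

    @property
    def leaves(self) -> list[str]:
        return sorted({p.leaf for p in self.paths})

    @property
    def has_loop(self) -> bool:
        return any(p.side_label is not None for p in self.paths)


@dataclass(frozen=True)
class KineticsSpec:
    """Marker kinetics: per marker, a list of (path scope, primitive).

    A scope of ``None`` applies on every path; otherwise the primitive is
    active only on the named paths.  Markers absent from a path default to
    the constant 0 curve, so every marker is defined on every branch.
    """

    markers: tuple[tuple[str, tuple[tuple[frozenset | None, Kinetic], ...]], ...]

    @property
    def marker_names(self) -> list[str]:
        return [m for m, _ in self.markers]

    def evaluate(self, marker: str, path_name: str, t: np.ndarray) -> np.ndarray:
        out = np.zeros_like(np.asarray(t, dtype=np.float64))
        for name, rules in self.markers:
            if name != marker:
                continue
            for scope, kin in rules:
                if scope is None or path_name in scope:
                    out = out + kin(t)
        return out


# ---------------------------------------------------------------------------
# Generation
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """An EventTable plus row-aligned ground truth and the generator config."""

    table: EventTable
    truth: pd.DataFrame  # columns: path, stage, latent_time, side
    config: dict
    seed: int

    @property
    def n_events(self) -> int:
        return self.table.n_events


def generate(
    topology: TopologySpec,
    kinetics: KineticsSpec,
    n_cells: int,
    noise_sd: float,
    seed: int,
) -> SyntheticDataset:
    """Draw ``n_cells`` events from the branching model.

    Per event: a path is chosen by path weight, latent time uniformly on
    [0, 1], marker values are the summed kinetic primitives plus Gaussian
    noise (sd ``noise_sd``) on the arcsinh-like transformed scale.
    Deterministic given (specs, n_cells, noise_sd, seed).
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    weights = np.array([p.weight for p in topology.paths])
    path_idx = rng.choice(len(topology.paths), size=n_cells, p=weights / weights.sum())
    t = rng.uniform(0.0, 1.0, size=n_cells)

    markers = kinetics.marker_names
    values = np.zeros((n_cells, len(markers)))
    stage = np.empty(n_cells, dtype=object)
    side = np.empty(n_cells, dtype=object)
    path_name = np.empty(n_cells, dtype=object)
    for pi, path in enumerate(topology.paths):
        mask = path_idx == pi
        if not mask.any():
            continue
        tm = t[mask]
        for mj, marker in enumerate(markers):
            values[mask, mj] = kinetics.evaluate(marker, path.name, tm)
        stage[mask] = path.stage_at(tm)
        side[mask] = path.side_label
        path_name[mask] = path.name
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)

    table = EventTable(
        values=values,
        marker_names=list(markers),
        sample_id=np.repeat(np.array(["synthetic"], dtype=object), n_cells),
        gate_label=stage.copy(),
        transform_state="arcsinh(5)",
    )
    truth = pd.DataFrame(
        {"path": path_name, "stage": stage, "latent_time": t, "side": side}
    )
    config = {
        "n_cells": n_cells,
        "noise_sd": noise_sd,
        "paths": [p.name for p in topology.paths],
        "markers": markers,
    }
    return SyntheticDataset(table=table, truth=truth, config=config, seed=seed)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_TRUNK = (
    ("stem", 0.00, 0.12),
    ("proB", 0.12, 0.24),
    ("preBI", 0.24, 0.36),
    ("preBII", 0.36, 0.48),
    ("immature", 0.48, 0.58),
    ("transitional", 0.58, 0.68),
)


def preset_bcell_like(n_markers: int = 30) -> tuple[TopologySpec, KineticsSpec]:
    """B-lymphopoiesis-like branching preset with a rare distal plasma tip.

    Topology: a six-stage trunk, a kappa/lambda split at latent time 0.68,
    an effector/memory split at 0.80 on each light-chain arm, and a
    low-weight plasma-cell path that continues past the kappa memory stage
    through a long corridor of marker change.  The corridor carries ~0.3% of
    cells, so pseudotime anchored at the origin alone rarely routes walks to
    the plasma tip -- the scenario that expert-set endpoints are meant to fix.

    Kinetics follow the canonical B-cell ordering: CD34 switches off first,
    TdT peaks in pro-B/pre-BI, CD10 mid, surface IgM rises in transitional
    cells, light chains after the kappa/lambda split, CD27/CD73 in the memory
    stages and CD38/CD138 only along the plasma corridor.
    """
    if n_markers < 10:
        raise ValueError("the panel preset needs at least 10 markers")

    k_paths = frozenset({"eff_k", "mem_k", "plasma_k"})
    l_paths = frozenset({"eff_l", "mem_l", "plasma_l"})
    mem_paths = frozenset({"mem_k", "mem_l", "plasma_k", "plasma_l"})
    late_paths = frozenset({"eff_k", "mem_k", "eff_l", "mem_l", "plasma_k", "plasma_l"})
    plasma = frozenset({"plasma_k", "plasma_l"})

    def arm(name: str, naive: str, tip: str) -> LineagePath:
        return LineagePath(
            name=name,
            weight=0.244,
            stages=_TRUNK + ((naive, 0.68, 0.80), (tip, 0.80, 1.00)),
        )

    def pc_path(name: str, naive: str, mem: str, chain: str) -> LineagePath:
        return LineagePath(
            name=name,
            weight=0.012,
            stages=_TRUNK
            + (
                (naive, 0.68, 0.76),
                (mem, 0.76, 0.84),
                (f"pc_corridor_{chain}", 0.84, 0.93),
                (f"plasma_cell_{chain}", 0.93, 1.00),
            ),
        )

    paths = (
        arm("eff_k", "naive_k", "nat_eff_k"),
        arm("mem_k", "naive_k", "sw_mem_k"),
        arm("eff_l", "naive_l", "nat_eff_l"),
        arm("mem_l", "naive_l", "sw_mem_l"),
        pc_path("plasma_k", "naive_k", "sw_mem_k", "k"),
        pc_path("plasma_l", "naive_l", "sw_mem_l", "l"),
    )
    topology = TopologySpec(paths=paths)

    def k(kind, center, width, amplitude):
        return Kinetic(kind=kind, center=center, width=width, amplitude=amplitude)

    named: list[tuple[str, tuple[tuple[frozenset | None, Kinetic], ...]]] = [
        ("CD34", (((None), k("logistic_down", 0.13, 0.03, 3.5)),)),
        ("CD19", ((None, k("logistic_up", 0.14, 0.03, 3.5)),)),
        ("iCD79a", ((None, k("logistic_up", 0.10, 0.03, 3.0)),)),
        ("iTdT", ((None, k("bump", 0.22, 0.07, 3.5)),)),
        ("iPAX-5", ((None, k("logistic_up", 0.18, 0.04, 2.5)),)),
        ("CD127", ((None, k("bump", 0.15, 0.06, 2.0)),)),
        ("CD10", ((None, k("bump", 0.33, 0.09, 3.5)),)),
        ("iKi-67", ((None, k("bump", 0.30, 0.10, 2.0)),)),
        ("CD9", ((None, k("bump", 0.30, 0.08, 2.0)),)),
        ("iBcl-2", ((None, k("logistic_up", 0.50, 0.10, 1.5)),)),
        ("CXCR4", ((None, k("logistic_down", 0.50, 0.08, 2.5)),)),
        ("CD20", ((None, k("logistic_up", 0.55, 0.06, 3.0)),)),
        ("CD24", ((None, k("bump", 0.62, 0.10, 2.5)),)),
        ("sIgM", ((None, k("logistic_up", 0.62, 0.05, 3.5)),)),
        ("IgD", ((None, k("logistic_up", 0.70, 0.05, 2.5)),)),
        ("CXCR5", ((None, k("logistic_up", 0.66, 0.06, 2.0)),)),
        ("kappa", ((k_paths, k("logistic_up", 0.74, 0.04, 3.5)),)),
        ("lambda", ((l_paths, k("logistic_up", 0.74, 0.04, 3.5)),)),
        ("CD27", ((late_paths, k("logistic_up", 0.86, 0.05, 3.0)),)),
        ("CD73", ((mem_paths, k("logistic_up", 0.82, 0.05, 2.5)),)),
        ("CD38", ((plasma, k("logistic_up", 0.90, 0.018, 2.2)),)),
        ("CD138", ((plasma, k("logistic_up", 0.94, 0.02, 1.6)),)),
        ("CD45", ((None, Kinetic("constant", amplitude=2.0)),)),
        ("HLA-DR", ((None, k("logistic_down", 0.85, 0.08, 2.0)),)),
    ]
    n_named = len(named)
    for i in range(n_named, n_markers):
        named.append((f"BG{i - n_named + 1}", ((None, Kinetic("constant", amplitude=0.0)),)))
    return topology, KineticsSpec(markers=tuple(named[:n_markers]))


def preset_loop(radius: float = 1.0, n_markers: int = 10) -> tuple[TopologySpec, KineticsSpec]:
    """Two parallel routes between the same endpoints, arranged as an annulus.

    The first two markers trace the upper and lower semicircle of a circle of
    the given radius as latent time runs 0 -> 1, so the noiseless point cloud
    is an annulus with exactly one dominant first-homology class.  The loop
    side ("upper"/"lower") is recorded in the ground truth.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_markers < 2:
        raise ValueError("the loop preset needs at least 2 markers")
    stages_u = (("start", 0.0, 0.15), ("route_upper", 0.15, 0.85), ("end", 0.85, 1.0))
    stages_l = (("start", 0.0, 0.15), ("route_lower", 0.15, 0.85), ("end", 0.85, 1.0))
    topology = TopologySpec(
        paths=(
            LineagePath("upper", 0.5, stages_u, side_label="upper"),
            LineagePath("lower", 0.5, stages_l, side_label="lower"),
        )
    )
    upper = frozenset({"upper"})
    lower = frozenset({"lower"})
    markers: list[tuple[str, tuple[tuple[frozenset | None, Kinetic], ...]]] = [
        ("M1", ((None, Kinetic("arc_cos", amplitude=radius)),)),
        (
            "M2",
            (
                (upper, Kinetic("arc_sin", amplitude=radius)),
                (lower, Kinetic("arc_sin_neg", amplitude=radius)),
            ),
        ),
    ]
    for i in range(2, n_markers):
        markers.append((f"BG{i - 1}", ((None, Kinetic("constant", amplitude=0.0)),)))
    return topology, KineticsSpec(markers=tuple(markers))


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def export_dataset(ds: SyntheticDataset, out_dir: str | FsPath, cofactor: float = 5.0) -> dict:
    """Write the dataset as raw-scale FCS + panel CSV + gate CSV + truth CSV.

    Values are sinh-back-transformed so that reading the FCS and applying the
    standard arcsinh exercises the full preprocessing path.
    """
    out = FsPath(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    raw = np.sinh(ds.table.values) * cofactor
    fcs_path = out / "synthetic.fcs"
    write_fcs(fcs_path, raw, ds.table.marker_names)
    panel_path = out / "panel.csv"
    with open(panel_path, "w", newline="") as fh:
        fh.write("channel,marker,use\n")
        for name in ds.table.marker_names:
            fh.write(f"{name},{name},1\n")
    gates_path = out / "gates.csv"
    with open(gates_path, "w", newline="") as fh:
        fh.write("sample_id,event_index,label\n")
        for i, label in enumerate(ds.table.gate_label):
            fh.write(f"synthetic,{i},{label}\n")
    truth_path = out / "truth.csv"
    ds.truth.to_csv(truth_path, index=False)
    config_path = out / "generator.json"
    config_path.write_text(json.dumps({"seed": ds.seed, **ds.config}, indent=2))
    return {
        "fcs": str(fcs_path),
        "panel": str(panel_path),
        "gates": str(gates_path),
        "truth": str(truth_path),
        "config": str(config_path),
    }
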