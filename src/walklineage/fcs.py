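"""Reading, writing and transforming cytometry event data.

The on-disk format is FCS (Flow Cytometry Standard) 3.0/3.1: a binary file
with an ASCII header, a delimited TEXT segment of keyword/value pairs and a
DATA segment of packed event values.  This module implements a reader for
FCS 3.0/3.1 (list-mode, float or integer data, single dataset) and a writer
for FCS 3.1 (float32 little-endian), plus the standard arcsinh
variance-stabilizing transform, multi-sample concatenation with gate-label
filtering, and export of "enhanced" FCS files carrying derived per-cell
parameters (2D embedding coordinates, pseudotime, trajectory membership).
"""

from __future__ import annotations

import csv
import struct
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PanelMap",
    "EventTable",
    "DerivedChannels",
    "FcsFormatError",
    "read_fcs",
    "write_fcs",
    "arcsinh_transform",
    "concatenate",
    "export_enhanced_fcs",
    "read_gate_csv",
    "apply_gate_labels",
    "read_panel_csv",
]

#: Reserved prefix for derived channels in enhanced FCS files.
DERIVED_PREFIX = "TVB_"


class FcsFormatError(ValueError):
    """Raised when an FCS file cannot be parsed or written."""


# ---------------------------------------------------------------------------
# Panel map
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PanelMap:
    """Mapping from instrument channel ids to marker names.

    ``entries`` is a sequence of ``(channel_id, marker, use_for_analysis)``
    tuples.  Channel ids must be unique, analysis markers must be unique and
    at least one channel must be flagged for analysis.
    """

    entries: tuple[tuple[str, str, bool], ...]

    def __post_init__(self) -> None:
        channels = [e[0] for e in self.entries]
        if len(set(channels)) != len(channels):
            raise ValueError("duplicate channel ids in panel map")
        markers = [e[1] for e in self.entries if e[2]]
        if not markers:
            raise ValueError("panel map selects no analysis markers")
        if len(set(markers)) != len(markers):
            raise ValueError("duplicate analysis marker names in panel map")

    @property
    def analysis_channels(self) -> list[tuple[str, str]]:
        return [(c, m) for c, m, use in self.entries if use]

    @property
    def analysis_markers(self) -> list[str]:
        return [m for _, m in self.analysis_channels]

    @classmethod
    def identity(cls, names: Sequence[str]) -> "PanelMap":
        return cls(tuple((n, n, True) for n in names))


def read_panel_csv(path: str | Path) -> PanelMap:
    """Read a panel map from CSV with columns channel,marker,use (use in 0/1)."""
    entries = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            entries.append(
                (row["channel"], row["marker"], row.get("use", "1").strip() in ("1", "true", "True"))
            )
    return PanelMap(tuple(entries))


# ---------------------------------------------------------------------------
# EventTable
# ---------------------------------------------------------------------------


@dataclass
class EventTable:
    """Events x markers intensity matrix with per-event metadata.

    This is the universal cell-level container: every downstream step (graph
    construction, walks, embedding, curves) consumes one.  ``transform_state``
    records whether values are raw or arcsinh-transformed, exactly once, so a
    double transform is impossible.
    """

    values: np.ndarray
    marker_names: list[str]
    sample_id: np.ndarray
    gate_label: np.ndarray | None = None
    transform_state: str = "raw"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] < 1:
            raise ValueError("values must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("event values contain non-finite entries")
        if len(self.marker_names) != self.values.shape[1]:
            raise ValueError("marker_names length does not match value columns")
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if self.sample_id.shape != (self.values.shape[0],):
            raise ValueError("sample_id must have one entry per event")
        if self.gate_label is not None:
            self.gate_label = np.asarray(self.gate_label, dtype=object)
            if self.gate_label.shape != (self.values.shape[0],):
                raise ValueError("gate_label must have one entry per event")

    @property
    def n_events(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]

    def marker_index(self, name: str) -> int:
        try:
            return self.marker_names.index(name)
        except ValueError:
            raise KeyError(f"marker {name!r} not in table (have {self.marker_names})") from None

    def marker(self, name: str) -> np.ndarray:
        return self.values[:, self.marker_index(name)]

    def subset(self, mask: np.ndarray) -> "EventTable":
        mask = np.asarray(mask)
        return EventTable(
            values=self.values[mask],
            marker_names=list(self.marker_names),
            sample_id=self.sample_id[mask],
            gate_label=None if self.gate_label is None else self.gate_label[mask],
            transform_state=self.transform_state,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.marker_names)
        df["sample_id"] = self.sample_id
        if self.gate_label is not None:
            df["gate_label"] = self.gate_label
        return df


@dataclass
class DerivedChannels:
    """Named per-event vectors computed by the pipeline.

    Conventional columns: ``TVB_vae1``/``TVB_vae2`` (embedding coordinates),
    ``TVB_pseudotime`` (nonnegative, finite), and one 0/1 membership
    indicator ``TVB_traj_<name>`` per selected trajectory.
    """

    columns: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.columns.values()}
        if len(lengths) > 1:
            raise ValueError("derived columns have inconsistent lengths")
        for name, v in self.columns.items():
            v = np.asarray(v, dtype=np.float64)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"derived column {name!r} contains non-finite values")
            if name == f"{DERIVED_PREFIX}pseudotime" and np.any(v < 0):
                raise ValueError("pseudotime channel must be nonnegative")
            if name.startswith(f"{DERIVED_PREFIX}traj_") and not np.all(np.isin(v, (0.0, 1.0))):
                raise ValueError(f"membership column {name!r} must be 0/1")
            self.columns[name] = v

    @property
    def n_events(self) -> int:
        return len(next(iter(self.columns.values()))) if self.columns else 0

    @classmethod
    def assemble(
        cls,
        n_events: int,
        embedding: np.ndarray | None = None,
        pseudotime: np.ndarray | None = None,
        memberships: dict[str, np.ndarray] | None = None,
    ) -> "DerivedChannels":
        cols: dict[str, np.ndarray] = {}
        if embedding is not None:
            emb = np.asarray(embedding, dtype=np.float64)
            if emb.shape != (n_events, 2):
                raise ValueError("embedding must be n_events x 2")
            cols[f"{DERIVED_PREFIX}vae1"] = emb[:, 0]
            cols[f"{DERIVED_PREFIX}vae2"] = emb[:, 1]
        if pseudotime is not None:
            cols[f"{DERIVED_PREFIX}pseudotime"] = np.asarray(pseudotime, dtype=np.float64)
        for name, ind in (memberships or {}).items():
            cols[f"{DERIVED_PREFIX}traj_{name}"] = np.asarray(ind, dtype=np.float64)
        for name, v in cols.items():
            if len(v) != n_events:
                raise ValueError(f"derived column {name!r} has length {len(v)}, expected {n_events}")
        return cls(cols)


# ---------------------------------------------------------------------------
# FCS binary reading
# ---------------------------------------------------------------------------


def _parse_text_segment(raw: bytes) -> dict[str, str]:
    if not raw:
        raise FcsFormatError("empty TEXT segment")
    delim = raw[0:1]
    body = raw[1:]
    if body.endswith(delim):
        body = body[:-1]
    # A doubled delimiter escapes a literal delimiter inside a value; the
    # split therefore yields empty tokens that must be rejoined.
    tokens = body.split(delim)
    merged: list[str] = []
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        while i + 1 < len(tokens) and tokens[i + 1] == "" and i + 2 < len(tokens):
            tok = tok + delim.decode("latin-1") + tokens[i + 2]
            i += 2
        merged.append(tok)
        i += 1
    if len(merged) % 2 != 0:
        merged = merged[:-1]
    keywords = {}
    for k, v in zip(merged[::2], merged[1::2]):
        keywords[k.decode("latin-1").strip().upper() if isinstance(k, bytes) else k] = v
    # decode bytes
    return {
        (k.decode("latin-1").strip().upper() if isinstance(k, bytes) else str(k).strip().upper()): (
            v.decode("latin-1") if isinstance(v, bytes) else str(v)
        )
        for k, v in keywords.items()
    }


def _read_fcs_arrays(path: str | Path) -> tuple[dict[str, str], list[str], np.ndarray]:
    """Parse a single-dataset FCS 3.0/3.1 file into (keywords, channel names, data)."""
    path = Path(path)
    blob = path.read_bytes()
    if len(blob) < 58:
        raise FcsFormatError(f"{path}: file too short for an FCS header (58 bytes required)")
    version = blob[0:6].decode("latin-1", errors="replace")
    if version not in ("FCS3.0", "FCS3.1"):
        raise FcsFormatError(f"{path}: unsupported FCS version {version!r} at offset 0")

    def _offset(lo: int, hi: int) -> int:
        text = blob[lo:hi].decode("latin-1", errors="replace").strip()
        if text == "":
            return 0
        try:
            return int(text)
        except ValueError:
            raise FcsFormatError(f"{path}: corrupt header field at offset {lo}: {text!r}") from None

    text_begin, text_end = _offset(10, 18), _offset(18, 26)
    data_begin, data_end = _offset(26, 34), _offset(34, 42)
    if text_begin <= 0 or text_end <= text_begin:
        raise FcsFormatError(f"{path}: corrupt TEXT offsets in header at offset 10")
    kw = _parse_text_segment(blob[text_begin : text_end + 1])

    if int(kw.get("$NEXTDATA", "0")) != 0:
        raise FcsFormatError(
            f"{path}: multi-dataset FCS files are not supported ($NEXTDATA != 0); "
            "split the file into one dataset per file"
        )
    if data_begin == 0:
        data_begin = int(kw.get("$BEGINDATA", "0"))
        data_end = int(kw.get("$ENDDATA", "0"))
    if data_begin <= 0 or data_end < data_begin:
        raise FcsFormatError(f"{path}: corrupt DATA offsets (begin={data_begin}, end={data_end})")

    n_par = int(kw["$PAR"])
    n_tot = int(kw["$TOT"])
    if n_tot == 0:
        raise FcsFormatError(f"{path}: file contains zero events")
    datatype = kw.get("$DATATYPE", "F").upper()
    byteord = kw.get("$BYTEORD", "1,2,3,4")
    endian = "<" if byteord.startswith("1") else ">"
    bits = [int(kw[f"$P{i}B"]) for i in range(1, n_par + 1)]
    if datatype == "F":
        if any(b != 32 for b in bits):
            raise FcsFormatError(f"{path}: $DATATYPE F requires 32-bit parameters")
        dtype = np.dtype(f"{endian}f4")
    elif datatype == "D":
        dtype = np.dtype(f"{endian}f8")
    elif datatype == "I":
        width = bits[0]
        if any(b != width for b in bits) or width not in (16, 32):
            raise FcsFormatError(f"{path}: only uniform 16/32-bit integer data supported")
        dtype = np.dtype(f"{endian}u{width // 8}")
    else:
        raise FcsFormatError(f"{path}: unsupported $DATATYPE {datatype!r}")

    raw = blob[data_begin : data_begin + n_par * n_tot * dtype.itemsize]
    expected = n_par * n_tot * dtype.itemsize
    if len(raw) != expected:
        raise FcsFormatError(
            f"{path}: DATA segment truncated at offset {data_begin} "
            f"(expected {expected} bytes, found {len(raw)})"
        )
    data = np.frombuffer(raw, dtype=dtype).reshape(n_tot, n_par).astype(np.float64)
    names = [kw.get(f"$P{i}N", f"P{i}") for i in range(1, n_par + 1)]
    return kw, names, data


def read_fcs(
    path: str | Path,
    panel: PanelMap | None = None,
    sample_id: str | None = None,
) -> EventTable:
    """Read an FCS file into a raw (untransformed) :class:`EventTable`.

    Channel names are substituted by marker names from ``panel`` and only
    channels flagged for analysis are retained; with ``panel=None`` every
    channel is kept under its $PnN name.  Event order is preserved.
    """
    kw, names, data = _read_fcs_arrays(path)
    sid = sample_id if sample_id is not None else Path(path).stem
    if panel is None:
        cols = list(range(len(names)))
        markers = list(names)
    else:
        cols, markers = [], []
        for channel, marker in panel.analysis_channels:
            if channel not in names:
                raise FcsFormatError(
                    f"{path}: channel {channel!r} required by the panel is missing "
                    f"(file channels: {names})"
                )
            cols.append(names.index(channel))
            markers.append(marker)
    return EventTable(
        values=data[:, cols],
        marker_names=markers,
        sample_id=np.repeat(np.array([sid], dtype=object), data.shape[0]),
        transform_state="raw",
    )


# ---------------------------------------------------------------------------
# FCS writing (FCS 3.1, float32, single dataset)
# ---------------------------------------------------------------------------


def write_fcs(
    path: str | Path,
    values: np.ndarray,
    channel_names: Sequence[str],
    extra_keywords: dict[str, str] | None = None,
) -> None:
    """Write a float32 little-endian FCS 3.1 file with one dataset."""
    values = np.ascontiguousarray(np.asarray(values), dtype="<f4")
    n_tot, n_par = values.shape
    if n_par != len(channel_names):
        raise FcsFormatError("channel_names length does not match value columns")
    delim = "/"
    for name in channel_names:
        if delim in name:
            raise FcsFormatError(f"channel name {name!r} contains the TEXT delimiter {delim!r}")

    def text_for(data_begin: int, data_end: int) -> bytes:
        kv = {
            "$BEGINANALYSIS": "0",
            "$ENDANALYSIS": "0",
            "$BEGINSTEXT": "0",
            "$ENDSTEXT": "0",
            "$BEGINDATA": str(data_begin),
            "$ENDDATA": str(data_end),
            "$BYTEORD": "1,2,3,4",
            "$DATATYPE": "F",
            "$MODE": "L",
            "$NEXTDATA": "0",
            "$TOT": str(n_tot),
            "$PAR": str(n_par),
        }
        ranges = np.maximum(np.ceil(np.nanmax(np.abs(values), axis=0)) + 1, 1)
        for i, name in enumerate(channel_names, start=1):
            kv[f"$P{i}N"] = str(name)
            kv[f"$P{i}B"] = "32"
            kv[f"$P{i}E"] = "0,0"
            kv[f"$P{i}R"] = str(int(ranges[i - 1]))
        kv.update(extra_keywords or {})
        parts = [delim]
        for k, v in kv.items():
            parts.append(f"{k}{delim}{v}{delim}")
        return "".join(parts).encode("latin-1")

    data_bytes = values.tobytes()
    # Fixed-point iteration on offsets: the TEXT segment mentions the DATA
    # offsets, whose width can change the TEXT length.
    text_begin = 58
    data_begin = 0
    for _ in range(4):
        text = text_for(data_begin, data_begin + len(data_bytes) - 1 if data_begin else 0)
        new_data_begin = text_begin + len(text)
        if new_data_begin == data_begin:
            break
        data_begin = new_data_begin
    text = text_for(data_begin, data_begin + len(data_bytes) - 1)
    data_begin = text_begin + len(text)
    data_end = data_begin + len(data_bytes) - 1

    header = (
        b"FCS3.1    "
        + f"{text_begin:>8d}".encode()
        + f"{text_begin + len(text) - 1:>8d}".encode()
        + (f"{data_begin:>8d}".encode() if data_begin <= 99_999_999 else b"       0")
        + (f"{data_end:>8d}".encode() if data_end <= 99_999_999 else b"       0")
        + f"{0:>8d}".encode()
        + f"{0:>8d}".encode()
    )
    assert len(header) == 58
    Path(path).write_bytes(header + text + data_bytes)


def export_enhanced_fcs(
    table: EventTable,
    derived: DerivedChannels,
    path: str | Path,
) -> None:
    """Export the table plus derived per-cell parameters as one FCS 3.1 file.

    The derived channels keep their reserved ``TVB_`` prefix so that manual
    analysis software can distinguish measured markers from computed ones.
    """
    if derived.columns and derived.n_events != table.n_events:
        raise ValueError(
            f"derived columns have {derived.n_events} rows, table has {table.n_events} events"
        )
    collisions = set(table.marker_names) & set(derived.columns)
    if collisions:
        raise ValueError(f"derived channel names collide with markers: {sorted(collisions)}")
    names = list(table.marker_names) + list(derived.columns)
    mat = np.column_stack([table.values] + [derived.columns[n] for n in derived.columns])
    write_fcs(path, mat, names, extra_keywords={"WALKLINEAGE_TRANSFORM": table.transform_state})


# ---------------------------------------------------------------------------
# Transforms and concatenation
# ---------------------------------------------------------------------------


def arcsinh_transform(table: EventTable, cofactor: float = 5.0) -> EventTable:
    """Apply ``asinh(x / cofactor)`` to every value; records the transform.

    The arcsinh with a cofactor of 5 is the mass-cytometry convention: it is
    linear near zero (where measurement noise dominates) and logarithmic for
    bright signals.  Strictly monotone, hence rank-preserving per marker.
    """
    if cofactor <= 0:
        raise ValueError("cofactor must be positive")
    if table.transform_state != "raw":
        raise ValueError(
            f"table already transformed ({table.transform_state}); refusing to double-transform"
        )
    return EventTable(
        values=np.arcsinh(table.values / cofactor),
        marker_names=list(table.marker_names),
        sample_id=table.sample_id.copy(),
        gate_label=None if table.gate_label is None else table.gate_label.copy(),
        transform_state=f"arcsinh({cofactor:g})",
    )


def concatenate(
    tables: Sequence[EventTable],
    keep_predicate: Callable[[object], bool] | Iterable[object] | None = None,
) -> EventTable:
    """Row-stack tables, keeping only events whose gate label passes the predicate.

    ``keep_predicate`` may be a callable over labels, a collection of accepted
    labels, or None (accept all).  Order is deterministic: input order, then
    event order within each table.
    """
    if not tables:
        raise ValueError("no tables to concatenate")
    ref = tables[0]
    for t in tables[1:]:
        if t.marker_names != ref.marker_names:
            diff = set(t.marker_names) ^ set(ref.marker_names)
            raise ValueError(f"marker name mismatch between tables; symmetric difference: {sorted(diff)}")
        if t.transform_state != ref.transform_state:
            raise ValueError(
                f"transform mismatch: {t.transform_state!r} vs {ref.transform_state!r}"
            )
    if keep_predicate is None:
        pred = lambda label: True  # noqa: E731
    elif callable(keep_predicate):
        pred = keep_predicate
    else:
        accepted = set(keep_predicate)
        pred = lambda label: label in accepted  # noqa: E731

    kept = []
    for t in tables:
        if keep_predicate is not None and t.gate_label is None:
            raise ValueError("a keep_predicate was given but a table has no gate labels")
        if t.gate_label is None:
            mask = np.ones(t.n_events, dtype=bool)
        else:
            mask = np.fromiter((bool(pred(lbl)) for lbl in t.gate_label), dtype=bool, count=t.n_events)
        kept.append(t.subset(mask))
    return EventTable(
        values=np.vstack([t.values for t in kept]),
        marker_names=list(ref.marker_names),
        sample_id=np.concatenate([t.sample_id for t in kept]),
        gate_label=(
            None
            if any(t.gate_label is None for t in kept)
            else np.concatenate([t.gate_label for t in kept])
        ),
        transform_state=ref.transform_state,
    )


# ---------------------------------------------------------------------------
# Sidecar gate labels
# ---------------------------------------------------------------------------


def read_gate_csv(path: str | Path) -> dict[tuple[str, int], str]:
    """Read a gate-label sidecar CSV with columns sample_id,event_index,label."""
    gates: dict[tuple[str, int], str] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample_id", "event_index", "label"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"gate CSV must have columns {sorted(required)}")
        for row in reader:
            gates[(row["sample_id"], int(row["event_index"]))] = row["label"]
    return gates


def apply_gate_labels(table: EventTable, gates: dict[tuple[str, int], str]) -> EventTable:
    """Attach gate labels keyed by (sample_id, 0-based event index in file order)."""
    labels = np.empty(table.n_events, dtype=object)
    counters: dict[str, int] = {}
    for i in range(table.n_events):
        sid = table.sample_id[i]
        idx = counters.get(sid, 0)
        counters[sid] = idx + 1
        labels[i] = gates.get((sid, idx))
    return replace(table, values=table.values.copy(), gate_label=labels)
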