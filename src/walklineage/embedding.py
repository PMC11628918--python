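"""Reusable parametric 2D embedding of cytometry events.

A small fully connected autoencoder trained on a
density-balanced subsample, producing a continuous 2D representation that
can be frozen and re-applied verbatim to newly acquired samples.  Three
ideas carry the design:

* **naive importance sampling** -- events are subsampled with weight
  proportional to inverse local density (distance to the k-th neighbor
  raised to an effective dimension), so numerically dominant populations are
  not overrepresented and training cost depends on the subsample, not the
  dataset;
* **continuity** -- the loss couples reconstruction error with a weak latent
  prior and a neighborhood-preservation term that penalizes separating
  mutual k-nearest neighbors in latent space, favoring a continuous sheet
  over isolated clusters;
* **reuse** -- the trained map is a pure function of (parameters, input):
  normalization statistics are frozen into the model, training is
  deterministic given the seed, and a save/load round trip reproduces
  outputs bit for bit.

The encoder/decoder are linear maps initialized at the 2-component principal
subspace plus small two-hidden-layer tanh corrections, trained jointly with
Adam.  Everything is plain numpy; no GPU or deep-learning runtime is needed.
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .fcs import EventTable

__all__ = [
    "SamplingWeights",
    "EmbeddingConfig",
    "EmbeddingModel",
    "density_balanced_sample",
    "train_embedding",
    "embed",
    "save_model",
    "load_model",
    "pca2",
    "knn_preservation",
]

MODEL_FORMAT_VERSION = "1"


@dataclass
class SamplingWeights:
    """Per-event inverse-density sampling weights, normalized to sum 1."""

    weights: np.ndarray
    k_density: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights < 0):
            raise ValueError("weights must be finite and nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must sum to 1")


def density_balanced_sample(
    table: EventTable,
    target: int,
    k_density: int = 15,
    seed: int = 0,
) -> tuple[EventTable, SamplingWeights]:
    """Weighted subsample with weight ~ (distance to k-th neighbor)^d_eff.

    The k-th neighbor distance is an inverse local-density estimate; raising
    it to d_eff = min(n_markers, 10) converts it to an inverse density, so
    the expected subsample composition is density-balanced.  Drawn without
    replacement, seeded.
    """
    if target <= 0:
        raise ValueError("target must be positive")
    n = table.n_events
    if target > n:
        raise ValueError(f"target {target} exceeds the number of events {n}")
    d_eff = min(table.n_markers, 10)
    nn = NearestNeighbors(n_neighbors=min(k_density + 1, n))
    nn.fit(table.values)
    dist, _ = nn.kneighbors(table.values)
    r = dist[:, -1]
    positive = r[r > 0]
    r = np.maximum(r, positive.min() if positive.size else 1.0)  # duplicates keep a floor
    w = r.astype(np.float64) ** d_eff
    w = w / w.sum()
    rng = np.random.default_rng(seed)
    if target == n:
        chosen = np.arange(n)
    else:
        chosen = np.sort(rng.choice(n, size=target, replace=False, p=w))
    return table.subset(chosen), SamplingWeights(weights=w, k_density=k_density)


# ---------------------------------------------------------------------------
# Model
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingConfig:
    subsample: int = 5000
    k_density: int = 15
    epochs: int = 40
    batch_size: int = 256
    learning_rate: float = 1e-3
    hidden: int = 64
    w_recon: float = 1.0
    w_prior: float = 0.01
    w_nbr: float = 0.5
    pair_k: int = 10
    pair_batch: int = 256


@dataclass
class EmbeddingModel:
    """Frozen parametric map markers -> 2D (plus decoder for reconstruction)."""

    params: dict[str, np.ndarray]
    center: np.ndarray  # per-marker median of the training subsample
    scale: np.ndarray  # per-marker MAD (scaled), floored
    marker_names: list[str]
    config: EmbeddingConfig
    seed: int
    n_loss_evaluations: int = 0
    final_loss: float = float("nan")


def _init_params(d: int, hidden: int, a_pca: np.ndarray, b_pca: np.ndarray, rng) -> dict:
    def glorot(fan_in, fan_out, gain=0.05):
        lim = gain * np.sqrt(6.0 / (fan_in + fan_out))
        return rng.uniform(-lim, lim, size=(fan_in, fan_out))

    return {
        "A": a_pca.copy(),
        "W1": glorot(d, hidden),
        "b1": np.zeros(hidden),
        "W2": glorot(hidden, hidden),
        "b2": np.zeros(hidden),
        "W3": glorot(hidden, 2),
        "b3": np.zeros(2),
        "B": b_pca.copy(),
        "U1": glorot(2, hidden),
        "c1": np.zeros(hidden),
        "U2": glorot(hidden, hidden),
        "c2": np.zeros(hidden),
        "U3": glorot(hidden, d),
        "c3": np.zeros(d),
    }


def _encode(p: dict, xs: np.ndarray):
    h1 = np.tanh(xs @ p["W1"] + p["b1"])
    h2 = np.tanh(h1 @ p["W2"] + p["b2"])
    z = xs @ p["A"] + h2 @ p["W3"] + p["b3"]
    return z, (h1, h2)


def _decode(p: dict, z: np.ndarray):
    g1 = np.tanh(z @ p["U1"] + p["c1"])
    g2 = np.tanh(g1 @ p["U2"] + p["c2"])
    xhat = z @ p["B"] + g2 @ p["U3"] + p["c3"]
    return xhat, (g1, g2)


def _encoder_backward(p, grads, xs, cache, dz):
    h1, h2 = cache
    grads["A"] += xs.T @ dz
    grads["W3"] += h2.T @ dz
    grads["b3"] += dz.sum(0)
    dh2 = (dz @ p["W3"].T) * (1 - h2**2)
    grads["W2"] += h1.T @ dh2
    grads["b2"] += dh2.sum(0)
    dh1 = (dh2 @ p["W2"].T) * (1 - h1**2)
    grads["W1"] += xs.T @ dh1
    grads["b1"] += dh1.sum(0)


def train_embedding(
    table: EventTable,
    config: EmbeddingConfig | None = None,
    seed: int = 0,
) -> EmbeddingModel:
    """Train the parametric embedding on a density-balanced subsample.

    Loss = w_recon * MSE(x, xhat) + w_prior * mean(z^2)
         + w_nbr * mean over mutual-kNN pairs of ||z_i - z_j||^2.

    The linear parts of encoder and decoder start at the 2-component
    principal subspace of the standardized subsample, so training refines an
    already sensible linear map.  Deterministic given (table, config, seed).
    """
    cfg = config or EmbeddingConfig()
    if table.n_events < 100:
        raise ValueError("training needs at least 100 events")
    if table.n_markers < 2:
        raise ValueError("training needs at least 2 markers")
    rng = np.random.default_rng(seed)

    target = min(cfg.subsample, table.n_events)
    sub, _ = density_balanced_sample(table, target, cfg.k_density, seed=int(rng.integers(2**31)))
    x = sub.values
    center = np.median(x, axis=0)
    mad = 1.4826 * np.median(np.abs(x - center), axis=0)
    # One global robust scale, not per-marker: arcsinh-transformed intensities
    # are already variance-stabilized, and per-marker rescaling would inflate
    # noise-only channels (switch-like markers have noise-level MADs) and
    # distort the marker-space geometry the rest of the pipeline works in.
    scale = np.full(x.shape[1], max(float(np.median(mad)), 1e-3))
    xs = (x - center) / scale
    m, d = xs.shape

    # PCA initialization of the linear skip connections
    u, s, vt = np.linalg.svd(xs - xs.mean(0), full_matrices=False)
    # one shared scale so the principal-plane geometry (aspect ratio) is kept
    sd = max(float(s[0]) / np.sqrt(m), 1e-6)
    a_pca = vt[:2].T / sd
    b_pca = vt[:2] * sd
    p = _init_params(d, cfg.hidden, a_pca, b_pca, rng)

    # mutual k-nearest-neighbor pairs of the subsample
    nn = NearestNeighbors(n_neighbors=min(cfg.pair_k + 1, m)).fit(xs)
    _, nbrs = nn.kneighbors(xs)
    pair_set = set()
    for i in range(m):
        for j in nbrs[i, 1:]:
            if i in nbrs[j, 1:]:
                pair_set.add((min(i, int(j)), max(i, int(j))))
    pairs = np.array(sorted(pair_set), dtype=np.int64) if pair_set else np.empty((0, 2), dtype=np.int64)

    adam_m = {k: np.zeros_like(v) for k, v in p.items()}
    adam_v = {k: np.zeros_like(v) for k, v in p.items()}
    beta1, beta2, eps_adam = 0.9, 0.999, 1e-8
    step = 0
    n_evals = 0
    last_loss = np.nan

    for _epoch in range(cfg.epochs):
        order = rng.permutation(m)
        for start in range(0, m, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            xb = xs[idx]
            grads = {k: np.zeros_like(v) for k, v in p.items()}

            z, enc_cache = _encode(p, xb)
            xhat, (g1, g2) = _decode(p, z)
            nb = xb.shape[0]
            recon = np.mean((xhat - xb) ** 2)
            prior = np.mean(z**2)

            dxhat = cfg.w_recon * 2.0 * (xhat - xb) / (nb * d)
            grads["B"] += z.T @ dxhat
            grads["U3"] += g2.T @ dxhat
            grads["c3"] += dxhat.sum(0)
            dg2 = (dxhat @ p["U3"].T) * (1 - g2**2)
            grads["U2"] += g1.T @ dg2
            grads["c2"] += dg2.sum(0)
            dg1 = (dg2 @ p["U2"].T) * (1 - g1**2)
            grads["U1"] += z.T @ dg1
            grads["c1"] += dg1.sum(0)
            dz = dxhat @ p["B"].T + dg1 @ p["U1"].T
            dz += cfg.w_prior * 2.0 * z / (nb * 2)
            _encoder_backward(p, grads, xb, enc_cache, dz)

            nbr_loss = 0.0
            if pairs.shape[0] and cfg.w_nbr > 0:
                sel = pairs[rng.integers(0, pairs.shape[0], size=min(cfg.pair_batch, pairs.shape[0]))]
                xi, xj = xs[sel[:, 0]], xs[sel[:, 1]]
                zi, ci = _encode(p, xi)
                zj, cj = _encode(p, xj)
                diff = zi - zj
                np_pairs = sel.shape[0]
                nbr_loss = np.mean(np.sum(diff**2, axis=1))
                dzi = cfg.w_nbr * 2.0 * diff / np_pairs
                _encoder_backward(p, grads, xi, ci, dzi)
                _encoder_backward(p, grads, xj, cj, -dzi)

            loss = cfg.w_recon * recon + cfg.w_prior * prior + cfg.w_nbr * nbr_loss
            n_evals += 1
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training loss diverged at step {step} "
                    f"(recon={recon:.3g}, prior={prior:.3g}, nbr={nbr_loss:.3g}); "
                    "lower the learning rate"
                )
            last_loss = float(loss)

            step += 1
            for k in p:
                adam_m[k] = beta1 * adam_m[k] + (1 - beta1) * grads[k]
                adam_v[k] = beta2 * adam_v[k] + (1 - beta2) * grads[k] ** 2
                mhat = adam_m[k] / (1 - beta1**step)
                vhat = adam_v[k] / (1 - beta2**step)
                p[k] = p[k] - cfg.learning_rate * mhat / (np.sqrt(vhat) + eps_adam)

    return EmbeddingModel(
        params=p,
        center=center,
        scale=scale,
        marker_names=list(table.marker_names),
        config=cfg,
        seed=seed,
        n_loss_evaluations=n_evals,
        final_loss=last_loss,
    )


def embed(model: EmbeddingModel, table: EventTable) -> np.ndarray:
    """Project events into the frozen 2D coordinates (pure forward pass).

    Columns are matched to the model's markers by name, so column order in
    the incoming table does not matter; a missing marker is an error.
    """
    missing = [m for m in model.marker_names if m not in table.marker_names]
    if missing:
        raise ValueError(f"table is missing marker(s) required by the model: {missing}")
    cols = [table.marker_index(m) for m in model.marker_names]
    xs = (table.values[:, cols] - model.center) / model.scale
    z, _ = _encode(model.params, xs)
    return z


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------


def save_model(model: EmbeddingModel, path: str | Path) -> None:
    """Lossless single-file serialization (self-describing, versioned)."""
    meta = {
        "format_version": MODEL_FORMAT_VERSION,
        "config": asdict(model.config),
        "marker_names": model.marker_names,
        "seed": model.seed,
        "n_loss_evaluations": model.n_loss_evaluations,
        "final_loss": model.final_loss,
    }
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    np.savez(
        path,
        meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
        center=model.center,
        scale=model.scale,
        **arrays,
    )


def load_model(path: str | Path) -> EmbeddingModel:
    try:
        with np.load(path) as data:
            meta = json.loads(bytes(data["meta"]).decode())
            if meta.get("format_version") != MODEL_FORMAT_VERSION:
                raise ValueError(
                    f"model format version {meta.get('format_version')!r} "
                    f"not supported (expected {MODEL_FORMAT_VERSION!r})"
                )
            params = {
                k[len("param_") :]: data[k] for k in data.files if k.startswith("param_")
            }
            return EmbeddingModel(
                params=params,
                center=data["center"],
                scale=data["scale"],
                marker_names=list(meta["marker_names"]),
                config=EmbeddingConfig(**meta["config"]),
                seed=int(meta["seed"]),
                n_loss_evaluations=int(meta["n_loss_evaluations"]),
                final_loss=float(meta["final_loss"]),
            )
    except (OSError, KeyError, json.JSONDecodeError, ValueError, zipfile.BadZipFile) as exc:
        if isinstance(exc, ValueError) and "format version" in str(exc):
            raise
        raise ValueError(f"cannot load embedding model from {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Baselines and diagnostics
# ---------------------------------------------------------------------------


def pca2(x: np.ndarray) -> np.ndarray:
    """Plain 2-component principal projection (the linear baseline)."""
    xc = x - x.mean(0)
    _, _, vt = np.linalg.svd(xc, full_matrices=False)
    return xc @ vt[:2].T


def knn_preservation(x_high: np.ndarray, x_low: np.ndarray, k: int = 10) -> float:
    """Mean fraction of each point's k nearest neighbors preserved in 2D."""
    nh = NearestNeighbors(n_neighbors=k + 1).fit(x_high)
    nl = NearestNeighbors(n_neighbors=k + 1).fit(x_low)
    _, ih = nh.kneighbors(x_high)
    _, il = nl.kneighbors(x_low)
    keep = 0.0
    for a, b in zip(ih[:, 1:], il[:, 1:]):
        keep += len(set(a.tolist()) & set(b.tolist())) / k
    return keep / x_high.shape[0]
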