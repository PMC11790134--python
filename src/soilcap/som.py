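"""Self-organizing map with Davies–Bouldin cluster-count selection.

A rectangular-topology batch SOM is trained on column-standardized metal
concentrations: every epoch assigns each sample to its best-matching unit
(BMU, minimal Euclidean distance) and replaces each codebook vector by the
neighbourhood-weighted mean of the data, with a Gaussian neighbourhood
whose radius shrinks linearly from max(rows, cols)/2 to 1. Codebook
vectors are then clustered with k-means over a range of k; the k with the
lowest Davies–Bouldin index is selected and samples inherit the cluster of
their BMU (standard two-level SOM + k-means). Component planes — per-metal
slices of the codebook — expose inter-metal association via their spatial
correlation over units.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import davies_bouldin_score


def default_map_shape(n: int) -> tuple[int, int]:
    """Aspect-balanced grid with about 5*sqrt(n) units (heuristic map sizing)."""
    units = max(4, int(np.ceil(5.0 * np.sqrt(n))))
    rows = int(np.ceil(np.sqrt(units)))
    cols = int(np.ceil(units / rows))
    return rows, cols


def standardize(X: np.ndarray) -> np.ndarray:
    """Column z-scores; constant columns map to zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return (X - mu) / sd


@dataclass
class SOMResult:
    codebook: np.ndarray  # rows x cols x m
    bmu: np.ndarray  # n x 2 unit coordinates (row, col)
    quantization_error: float
    dbi_by_k: dict[int, float] = field(default_factory=dict)
    best_k: int | None = None
    unit_labels: np.ndarray | None = None  # rows*cols cluster ids
    cluster_of_sample: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.codebook.shape[0], self.codebook.shape[1]

    def flat_codebook(self) -> np.ndarray:
        r, c, m = self.codebook.shape
        return self.codebook.reshape(r * c, m)


def _bmu_indices(X: np.ndarray, flat: np.ndarray) -> np.ndarray:
    d2 = ((X[:, None, :] - flat[None, :, :]) ** 2).sum(axis=-1)
    return d2.argmin(axis=1)


def train_som(X: np.ndarray, rows: int | None = None, cols: int | None = None,
              epochs: int = 50, seed: int = 0) -> SOMResult:
    """Batch-train a rectangular SOM on a standardized n x m matrix.

    Deterministic given ``seed`` (codebook initialized from seeded uniform
    draws over the per-column data range). Warns when the map is sparse
    relative to the sample count.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if rows is None or cols is None:
        rows, cols = default_map_shape(n)
    if rows * cols < 4:
        raise ValueError("map must have at least 4 units")
    if n < rows * cols / 4:
        warnings.warn(f"sparse map: {rows * cols} units for {n} samples")

    rng = np.random.default_rng(seed)
    lo, hi = X.min(axis=0), X.max(axis=0)
    flat = rng.uniform(0.0, 1.0, (rows * cols, m)) * (hi - lo) + lo

    # unit coordinates on the grid for neighbourhood distances
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    units = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
    unit_d2 = ((units[:, None, :] - units[None, :, :]) ** 2).sum(axis=-1)

    sigma0 = max(rows, cols) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        sigma = sigma0 + (1.0 - sigma0) * frac  # linear sigma0 -> 1
        bmu = _bmu_indices(X, flat)
        h = np.exp(-unit_d2[:, bmu] / (2.0 * sigma ** 2))  # units x n
        denom = h.sum(axis=1, keepdims=True)
        nonempty = denom[:, 0] > 1e-300
        flat[nonempty] = (h[nonempty] @ X) / denom[nonempty]

    bmu = _bmu_indices(X, flat)
    qe = float(np.mean(np.linalg.norm(X - flat[bmu], axis=1)))
    bmu_coords = np.column_stack([bmu // cols, bmu % cols])
    return SOMResult(codebook=flat.reshape(rows, cols, m), bmu=bmu_coords,
                     quantization_error=qe)


def cluster_codebook(result: SOMResult, k_range=range(2, 11),
                     seed: int = 0, n_restarts: int = 10) -> SOMResult:
    """K-means over codebook vectors; pick k by minimal Davies–Bouldin index.

    k values outside [2, n_units - 1] are skipped (DBI is undefined at k = 1
    and at k = n_units every unit is its own cluster). Samples are labelled
    by their BMU's cluster. Mutates and returns ``result``.
    """
    flat = result.flat_codebook()
    n_units = flat.shape[0]
    dbi_by_k: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if not 2 <= k <= n_units - 1:
            continue
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
        labels = km.fit_predict(flat)
        if len(np.unique(labels)) < 2:
            warnings.warn(f"k={k}: degenerate clustering skipped")
            continue
        dbi_by_k[k] = float(davies_bouldin_score(flat, labels))
        labels_by_k[k] = labels
    if not dbi_by_k:
        raise ValueError("no valid k in range")
    best_k = min(dbi_by_k, key=dbi_by_k.get)
    rows, cols = result.shape
    unit_labels = labels_by_k[best_k]
    result.dbi_by_k = dbi_by_k
    result.best_k = best_k
    result.unit_labels = unit_labels
    flat_bmu = result.bmu[:, 0] * cols + result.bmu[:, 1]
    result.cluster_of_sample = unit_labels[flat_bmu]
    return result


def component_planes(result: SOMResult, metals=None) -> dict:
    """Per-variable codebook slices keyed by metal name (or column index)."""
    r, c, m = result.codebook.shape
    keys = list(metals) if metals is not None else list(range(m))
    return {keys[j]: result.codebook[:, :, j] for j in range(m)}


def plane_correlations(result: SOMResult, metals=None):
    """Pearson r between component planes over units (m x m DataFrame)."""
    import pandas as pd

    flat = result.flat_codebook()
    m = flat.shape[1]
    keys = list(metals) if metals is not None else list(range(m))
    r = np.corrcoef(flat.T)
    return pd.DataFrame(r, index=keys, columns=keys)
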