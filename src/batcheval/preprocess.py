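"""Normalization, per-observation/per-gene summaries, embeddings and kNN graphs.

Every downstream metric operates on these primitives: the min-max + log1p
normalization applied to the merged matrix, per-observation total counts
(the quantity the statistical battery tests), per-gene mean/variance
summaries, PCA/UMAP embeddings, and exact k-nearest-neighbor graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


@dataclass
class NeighborGraph:
    """Fixed-size neighborhood graph in a named embedding.

    ``indices[i]`` holds the ids of observation ``i``'s ``k`` nearest
    neighbors by Euclidean distance, self excluded, ties broken toward the
    lower index.
    """

    indices: np.ndarray  # (N, k) int
    k: int
    metric: str = "euclidean"
    embedding_name: str = "pca"

    def __post_init__(self) -> None:
        self.indices = np.asarray(self.indices, dtype=int)
        n, k = self.indices.shape
        if k != self.k:
            raise ValueError(f"indices have {k} columns, expected k={self.k}")
        if (self.indices == np.arange(n)[:, None]).any():
            raise ValueError("neighbor graph contains self-loops")
        if self.indices.min() < 0 or self.indices.max() >= n:
            raise ValueError("neighbor indices out of range")

    @property
    def n_obs(self) -> int:
        return self.indices.shape[0]


def minmax_log_normalize(matrix: np.ndarray) -> np.ndarray:
    """Min-max scale the whole matrix to [0, 1], then log1p.

    x_hat = log1p((x - x_min) / (x_max - x_min)) with x_min/x_max the global
    minimum and maximum expression in the dataset, so batches stay on one
    common scale; output lies in [0, log 2].

    A constant matrix (x_max == x_min) maps to all zeros with a warning.
    """
    matrix = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(matrix)):
        raise ValueError("matrix contains non-finite values")
    if matrix.size and matrix.min() < 0:
        raise ValueError("matrix contains negative values")
    x_min, x_max = matrix.min(), matrix.max()
    if x_max == x_min:
        warnings.warn("constant matrix: min-max normalization is degenerate, returning zeros")
        return np.zeros_like(matrix)
    return np.log1p((matrix - x_min) / (x_max - x_min))


def per_cell_total_counts(dataset) -> np.ndarray:
    """Total raw counts per observation (row sums of the count matrix)."""
    return np.asarray(dataset.matrix, dtype=float).sum(axis=1)


def per_gene_mean_variance(dataset, by_batch: bool = True):
    """Gene-wise mean and population variance (ddof 0), per batch or global.

    Returns a dict ``{batch_name: (means, variances)}`` when ``by_batch``,
    else a single ``(means, variances)`` pair.
    """
    m = np.asarray(dataset.matrix, dtype=float)
    if not by_batch:
        return m.mean(axis=0), m.var(axis=0, ddof=0)
    out = {}
    batch = np.asarray(dataset.batch).astype(str)
    for name in sorted(set(batch)):
        sub = m[batch == name]
        out[name] = (sub.mean(axis=0), sub.var(axis=0, ddof=0))
    return out


def _fix_signs(components: np.ndarray, scores: np.ndarray):
    # deterministic sign convention: largest-magnitude loading positive
    for j in range(components.shape[0]):
        i = np.argmax(np.abs(components[j]))
        if components[j, i] < 0:
            components[j] *= -1
            scores[:, j] *= -1
    return components, scores


def pca_embed(dataset, n_components: int = 50, seed: int = 0,
              layer: str = "normalized") -> np.ndarray:
    """PCA scores of the normalized layer, stored under embedding "pca".

    Sign convention is fixed (largest-magnitude loading positive) so repeated
    runs are bit-identical regardless of LAPACK sign freedom.
    """
    from sklearn.decomposition import PCA

    if layer not in dataset.layers:
        if layer == "normalized":
            dataset.layers["normalized"] = minmax_log_normalize(dataset.matrix)
        else:
            raise KeyError(f"layer {layer!r} not found")
    x = dataset.layers[layer]
    max_comp = min(x.shape) - 1
    if n_components >= min(x.shape):
        raise ValueError(
            f"n_components={n_components} must be < min(N, genes)={min(x.shape)}"
        )
    pca = PCA(n_components=n_components, svd_solver="full", random_state=seed)
    scores = pca.fit_transform(x)
    _fix_signs(pca.components_, scores)
    dataset.embeddings["pca"] = scores
    return scores


def umap_embed(dataset, n_neighbors: int = 15, seed: int = 0) -> np.ndarray:
    """2-D UMAP layout of the PCA scores, stored under embedding "umap".

    Display-oriented: metrics default to the PCA space because UMAP distorts
    local neighborhood composition.
    """
    if "pca" not in dataset.embeddings:
        raise KeyError('embedding "pca" required before UMAP; run pca_embed first')
    x = dataset.embeddings["pca"]
    if x.shape[0] < n_neighbors + 1:
        raise ValueError(
            f"N={x.shape[0]} too small for n_neighbors={n_neighbors}"
        )
    import umap

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # umap warns that a fixed seed disables parallelism
        reducer = umap.UMAP(n_components=2, n_neighbors=n_neighbors,
                            random_state=seed)
        coords = reducer.fit_transform(x)
    dataset.embeddings["umap"] = np.asarray(coords, dtype=float)
    return dataset.embeddings["umap"]


def exact_knn(points: np.ndarray, k: int, chunk: int = 2048) -> np.ndarray:
    """Exact k nearest neighbors by Euclidean distance, self excluded.

    Stable argsort on the full distance row breaks ties toward the lower
    index. Chunked over query rows to bound memory at O(chunk * N).
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be < N={n}")
    sq = (points ** 2).sum(axis=1)
    out = np.empty((n, k), dtype=int)
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] - 2.0 * points[start:stop] @ points.T + sq[None, :]
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[np.arange(stop - start), rows] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")
        out[start:stop] = order[:, :k]
    return out


def knn_neighbors(dataset, embedding_name: str = "pca", k: int = 25) -> NeighborGraph:
    """Exact kNN graph on a named embedding."""
    if embedding_name not in dataset.embeddings:
        raise KeyError(
            f"unknown embedding {embedding_name!r}; available: "
            f"{sorted(dataset.embeddings)}"
        )
    idx = exact_knn(dataset.embeddings[embedding_name], k=k)
    return NeighborGraph(indices=idx, k=k, embedding_name=embedding_name)


def prepare_embeddings(dataset, n_components: int = 50, n_neighbors: int = 15,
                       seed: int = 0, with_umap: bool = True):
    """Default pipeline: normalize -> PCA -> (optionally) UMAP."""
    if "normalized" not in dataset.layers:
        dataset.layers["normalized"] = minmax_log_normalize(dataset.matrix)
    n_components = min(n_components, min(dataset.matrix.shape) - 1)
    pca_embed(dataset, n_components=n_components, seed=seed)
    if with_umap:
        umap_embed(dataset, n_neighbors=min(n_neighbors, dataset.n_obs - 1), seed=seed)
    return dataset
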