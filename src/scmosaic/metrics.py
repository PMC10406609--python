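"""Evaluation metrics: LISI-style label enrichment, neighbor rank distance,
and KNN smoothing references for imputation benchmarks.

All KNN computations use Euclidean distance, exclude the query point itself,
and break distance ties by ascending cell index so results are deterministic.
Neighbor search is exact (brute force) — the intended problem sizes are a few
thousand cells.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist
from sklearn.decomposition import PCA, TruncatedSVD

from .diffexp import tfidf_transform

__all__ = ["knn_indices", "lisi_enrichment", "rank_distance",
           "smooth_atac", "smooth_rna"]


def knn_indices(coords: np.ndarray, k: int,
                query: np.ndarray | None = None) -> np.ndarray:
    """Indices of the k nearest neighbors per row, self excluded.

    Ties in distance are broken by ascending index via stable lexsort.
    """
    coords = np.asarray(coords, float)
    n = coords.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of cells")
    d = cdist(query if query is not None else coords, coords)
    if query is None:
        np.fill_diagonal(d, np.inf)
    order = np.lexsort((np.broadcast_to(np.arange(n), d.shape), d), axis=1)
    return order[:, :k]


def lisi_enrichment(coords: np.ndarray, labels, k: int) -> float:
    """Same-label KNN fraction normalized by its random expectation.

    s_i = (1/k) * #{neighbors of i sharing i's label}; the score is
    mean(s) / sum_l p_l^2 where p_l are the label proportions. A score of 1
    indicates perfect mixing; larger values indicate label separation.
    """
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 1:
        raise ValueError("labels required")
    nn = knn_indices(coords, k)
    same = (labels[nn] == labels[:, None]).mean(axis=1)
    p = np.bincount(np.unique(labels, return_inverse=True)[1]) / len(labels)
    expected = float(np.sum(p**2))
    return float(same.mean() / expected)


def rank_distance(coords_a: np.ndarray, coords_b: np.ndarray,
                  symmetric: bool = False) -> tuple[np.ndarray, float]:
    """Neighbor rank of each cell's counterpart representation.

    Both representations must live in the same space; the search set is the
    union of all 2N points. delta(c_a, c_b) is the minimal K at which c_b
    appears among the K nearest neighbors of c_a (so delta >= 1, and
    delta = 1 means the counterpart is the nearest neighbor). With
    ``symmetric`` the per-cell value is max(delta_ab, delta_ba).
    """
    a = np.asarray(coords_a, float)
    b = np.asarray(coords_b, float)
    if a.shape != b.shape:
        raise ValueError("representations must be matched per cell")
    n = a.shape[0]
    pool = np.vstack([a, b])

    def _delta(src_rows: np.ndarray, target_idx: np.ndarray) -> np.ndarray:
        d = cdist(pool[src_rows], pool)
        d[np.arange(len(src_rows)), src_rows] = np.inf  # exclude self
        order = np.lexsort(
            (np.broadcast_to(np.arange(2 * n), d.shape), d), axis=1)
        ranks = np.empty(len(src_rows), dtype=int)
        for i in range(len(src_rows)):
            ranks[i] = int(np.where(order[i] == target_idx[i])[0][0]) + 1
        return ranks

    idx_a = np.arange(n)
    idx_b = np.arange(n, 2 * n)
    delta_ab = _delta(idx_a, idx_b)
    if symmetric:
        delta_ba = _delta(idx_b, idx_a)
        delta = np.maximum(delta_ab, delta_ba)
    else:
        delta = delta_ab
    return delta, float(delta.mean())


def smooth_atac(binary: sp.spmatrix | np.ndarray, n_components: int = 30,
                k: int = 50, seed: int = 0) -> np.ndarray:
    """KNN-smoothed accessibility: TF-IDF -> LSA -> neighbor-mean profile.

    Embeds cells with truncated SVD of the TF-IDF matrix (latent semantic
    analysis), finds each cell's k nearest neighbors there, and returns the
    mean binary profile of the neighbors (self excluded). Values in [0, 1].
    """
    x = np.asarray(sp.csr_matrix(binary).todense(), dtype=float)
    x = (x > 0).astype(float)
    n, j = x.shape
    if k < 1 or k >= n:
        raise ValueError("need 1 <= k < n_cells")
    if n_components >= min(n, j):
        raise ValueError("n_components must be < min(n_cells, n_features)")
    emb = TruncatedSVD(n_components=n_components,
                       random_state=seed).fit_transform(tfidf_transform(x))
    nn = knn_indices(emb, k)
    return x[nn].mean(axis=1)


def smooth_rna(counts: sp.spmatrix | np.ndarray, n_components: int = 30,
               k: int = 50, seed: int = 0) -> np.ndarray:
    """KNN-smoothed expression on library-scaled counts.

    PCA (on log1p of library-scaled counts) defines the neighborhood; the
    smoothed value is the neighbor mean of the library-scaled expression.
    """
    x = np.asarray(sp.csr_matrix(counts).todense(), dtype=float)
    n, g = x.shape
    if k < 1 or k >= n:
        raise ValueError("need 1 <= k < n_cells")
    if n_components >= min(n, g):
        raise ValueError("n_components must be < min(n_cells, n_features)")
    lib = x.sum(axis=1, keepdims=True)
    lib = np.where(lib > 0, lib, 1.0)
    scaled = x / lib
    emb = PCA(n_components=n_components,
              random_state=seed).fit_transform(np.log1p(scaled * 1e4))
    nn = knn_indices(emb, k)
    return scaled[nn].mean(axis=1)
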