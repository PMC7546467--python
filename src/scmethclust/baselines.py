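"""Non-probabilistic clustering baselines over sparse methylation data.

Three hierarchical methods mirror the field's standard approaches:

* Euclidean (region-based): pairwise Euclidean distances between cells'
  region mean methylation profiles, then complete-linkage clustering of
  the rows of that distance matrix;
* Hamming (CpG-based): proportion of discordant CpGs among commonly
  observed positions, then Ward linkage on the dissimilarity rows with
  Euclidean row distances;
* Pearson (CpG-based): 1 - r over commonly observed CpGs, Ward linkage
  with the same dissimilarity applied to the correlation-matrix rows.

All pairwise statistics use pairwise-complete observations; pairs with no
usable overlap are mean-filled (logged) before linkage.  The number of
clusters is chosen by the Calinski-Harabasz index on the same feature
rows the linkage used.  A pluggable density-clustering hook (PCA to at
most 20 components, then any features -> labels callable) provides one
extra partition.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import ClusterWarning, cut_tree, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA
from sklearn.metrics import calinski_harabasz_score

from .matrix import CellMethylationMatrix

logger = logging.getLogger(__name__)


class SparseFailureError(RuntimeError):
    """The input was too sparse for a pairwise statistic to be defined."""


@dataclass
class HierarchicalResult:
    """Dendrogram-derived partitions at 1..Kmax and the CH-chosen K."""

    method: str
    dissimilarity: np.ndarray          # N x N used to build the tree
    features: np.ndarray               # rows fed to linkage / CH
    linkage_matrix: np.ndarray
    partitions: dict[int, np.ndarray]  # K -> labels (0-based)
    best_k: int

    @property
    def best_labels(self) -> np.ndarray:
        return self.partitions[self.best_k]


def _fill_undefined(D: np.ndarray, method: str, fail_on_undefined: bool) -> np.ndarray:
    und = ~np.isfinite(D)
    np.fill_diagonal(und, False)
    if und.any():
        defined = D[np.isfinite(D) & ~np.eye(len(D), dtype=bool)]
        if defined.size == 0:
            raise SparseFailureError(
                f"{method}: no cell pair has a defined dissimilarity"
            )
        if fail_on_undefined:
            raise SparseFailureError(
                f"{method}: {int(und.sum()) // 2} undefined cell pairs"
            )
        logger.warning(
            "%s: mean-filling %d undefined cell pairs", method, int(und.sum()) // 2
        )
        D = D.copy()
        D[und] = defined.mean()
    return D


def _linkage_on_rows(D: np.ndarray, method: str) -> np.ndarray:
    """Linkage on the ROWS of a pairwise matrix (two-stage construction).

    The matrix rows are deliberately treated as feature vectors with
    Euclidean row dissimilarity, so scipy's heuristic warning about
    distance-like inputs does not apply.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ClusterWarning)
        return linkage(D, method=method, metric="euclidean")


def _cut_all(Z: np.ndarray, n: int, kmax: int) -> dict[int, np.ndarray]:
    ks = [k for k in range(1, min(kmax, n) + 1) if k < n]
    out = {}
    if ks:
        cuts = cut_tree(Z, n_clusters=ks)
        out = {k: cuts[:, i].astype(np.int64) for i, k in enumerate(ks)}
    if kmax >= n:
        out[n] = np.arange(n, dtype=np.int64)  # scipy cut at K=N is a no-op
    return out


def ch_best_k(features: np.ndarray, partitions: dict[int, np.ndarray]) -> int:
    """Calinski-Harabasz choice of K among the supplied partitions.

    CH(K) = [between-SS / (K-1)] / [within-SS / (N-K)] on the feature
    rows; K = 1 and K = N are excluded; ties go to the smaller K.
    """
    n = len(features)
    if n < 3:
        raise ValueError("CH selection needs at least 3 cells")
    best_k, best_score = None, -np.inf
    for k in sorted(partitions):
        if k < 2 or k >= n:
            continue
        labels = partitions[k]
        if len(np.unique(labels)) < 2:
            continue
        score = calinski_harabasz_score(features, labels)
        if score > best_score + 1e-12:
            best_k, best_score = k, score
    if best_k is None:
        raise ValueError("no partition with 2 <= K < N available")
    return best_k


# ----------------------------------------------------------------------
# pairwise dissimilarities (pairwise-complete)
# ----------------------------------------------------------------------

def pairwise_euclidean(table: np.ndarray) -> np.ndarray:
    """Euclidean distance over columns observed in both rows (NaN-aware)."""
    A = np.nan_to_num(table, nan=0.0)
    W = np.isfinite(table).astype(float)
    sq = A * A
    S = sq @ W.T + W @ sq.T - 2.0 * (A @ A.T)
    counts = W @ W.T
    with np.errstate(invalid="ignore"):
        D = np.sqrt(np.maximum(S, 0.0))
    D[counts == 0] = np.nan
    np.fill_diagonal(D, 0.0)
    return D


def pairwise_hamming(matrix: CellMethylationMatrix) -> np.ndarray:
    """Proportion of discordant CpGs among commonly observed positions."""
    X1 = (matrix.values == 1).astype(float)
    X0 = (matrix.values == 0).astype(float)
    disc = X1 @ X0.T + X0 @ X1.T
    common = (X1 + X0) @ (X1 + X0).T
    with np.errstate(invalid="ignore"):
        D = np.where(common > 0, disc / np.maximum(common, 1), np.nan)
    np.fill_diagonal(D, 0.0)
    return D


def pairwise_pearson_dissimilarity(values: np.ndarray) -> np.ndarray:
    """1 - Pearson r over commonly observed entries (NaN-aware).

    Entries in ``values`` are floats with NaN for missing.  Pairs with
    fewer than 2 common observations or zero variance are undefined.
    """
    n = len(values)
    obs = np.isfinite(values)
    D = np.full((n, n), np.nan)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            common = obs[i] & obs[j]
            if common.sum() < 2:
                continue
            a, b = values[i, common], values[j, common]
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                continue
            r = np.corrcoef(a, b)[0, 1]
            D[i, j] = D[j, i] = 1.0 - r
    return D


# ----------------------------------------------------------------------
# the three hierarchical methods
# ----------------------------------------------------------------------

def euclidean_clust(
    region_means: pd.DataFrame | np.ndarray,
    kmax: int = 10,
    fail_on_undefined: bool = False,
) -> HierarchicalResult:
    """Region-based clustering on region mean methylation.

    Two-stage: pairwise Euclidean cell distances first, then
    complete-linkage clustering of the rows of that distance matrix with
    Euclidean row dissimilarity.
    """
    table = np.asarray(region_means, dtype=float)
    if len(table) < 2:
        raise ValueError("need at least 2 cells")
    D = pairwise_euclidean(table)
    D = _fill_undefined(D, "euclidean", fail_on_undefined)
    Z = _linkage_on_rows(D, method="complete")
    parts = _cut_all(Z, len(table), kmax)
    best = ch_best_k(D, parts)
    return HierarchicalResult("euclidean", D, D, Z, parts, best)


def hamming_clust(
    matrix: CellMethylationMatrix,
    kmax: int = 10,
    fail_on_undefined: bool = False,
) -> HierarchicalResult:
    """CpG-based clustering on pairwise Hamming dissimilarities."""
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    D = pairwise_hamming(matrix)
    D = _fill_undefined(D, "hamming", fail_on_undefined)
    Z = _linkage_on_rows(D, method="ward")
    parts = _cut_all(Z, matrix.n_cells, kmax)
    best = ch_best_k(D, parts)
    return HierarchicalResult("hamming", D, D, Z, parts, best)


def pearson_clust(
    matrix: CellMethylationMatrix,
    kmax: int = 10,
    fail_on_undefined: bool = False,
) -> HierarchicalResult:
    """CpG-based clustering built entirely on Pearson correlation."""
    if matrix.n_cells < 2:
        raise ValueError("need at least 2 cells")
    vals = matrix.values.astype(float)
    vals[matrix.values == -1] = np.nan
    D1 = pairwise_pearson_dissimilarity(vals)
    D1 = _fill_undefined(D1, "pearson", fail_on_undefined)
    corr = 1.0 - D1  # correlation-matrix rows are the second-stage features
    D2 = pairwise_pearson_dissimilarity(corr)
    D2 = _fill_undefined(D2, "pearson", fail_on_undefined)
    np.fill_diagonal(D2, 0.0)
    # symmetrize against floating noise before condensing
    D2 = (D2 + D2.T) / 2.0
    Z = linkage(squareform(D2, checks=False), method="ward")
    parts = _cut_all(Z, matrix.n_cells, kmax)
    best = ch_best_k(corr, parts)
    return HierarchicalResult("pearson", D1, corr, Z, parts, best)


# ----------------------------------------------------------------------
# pre-imputation for sparse failures
# ----------------------------------------------------------------------

def pre_impute(table: np.ndarray, round_binary: bool = True) -> np.ndarray:
    """Column-mean imputation of a table with NaN (or -1) missing entries.

    Binary CpG matrices round the fill to {0, 1} with ties going to 1;
    region-mean tables keep the unrounded mean.  Columns with no observed
    value are filled with 0.5 and logged.
    """
    out = np.asarray(table, dtype=float).copy()
    out[out == -1] = np.nan
    obs = np.isfinite(out)
    counts = obs.sum(axis=0)
    sums = np.where(obs, out, 0.0).sum(axis=0)
    col_mean = np.where(counts > 0, sums / np.maximum(counts, 1), 0.5)
    n_blank = int((counts == 0).sum())
    if n_blank:
        logger.warning("pre_impute: %d fully missing columns set to 0.5", n_blank)
    if round_binary:
        fill = (col_mean >= 0.5).astype(float)
        fill = np.where(obs.any(axis=0), fill, 0.5)
    else:
        fill = col_mean
    return np.where(obs, out, fill[None, :])


# ----------------------------------------------------------------------
# density-method hook
# ----------------------------------------------------------------------

def _default_density_plugin(features: np.ndarray) -> np.ndarray:
    """Default density-based clusterer: HDBSCAN on the PC scores.

    Points flagged as noise are attached to the nearest cluster centroid;
    if everything is noise the result is a single cluster.
    """
    from sklearn.cluster import HDBSCAN

    labels = HDBSCAN(min_cluster_size=2, copy=True).fit_predict(features)
    clustered = labels >= 0
    if not clustered.any():
        return np.zeros(len(features), dtype=np.int64)
    if (~clustered).any():
        centroids = {
            k: features[labels == k].mean(axis=0) for k in np.unique(labels[clustered])
        }
        for i in np.where(~clustered)[0]:
            labels[i] = min(
                centroids, key=lambda k: np.linalg.norm(features[i] - centroids[k])
            )
    _, codes = np.unique(labels, return_inverse=True)
    return codes


def density_method(
    region_means: pd.DataFrame | np.ndarray,
    plugin=None,
    max_components: int = 20,
) -> np.ndarray:
    """One partition from a density-based clusterer on PCA scores.

    Region means are mean-imputed if sparse, projected onto at most
    ``max_components`` principal components, and handed to ``plugin``
    (a features -> labels callable; a mean-shift clusterer by default).
    """
    table = np.asarray(region_means, dtype=float)
    if np.isnan(table).any():
        table = pre_impute(table, round_binary=False)
    n_comp = min(max_components, table.shape[0] - 1, table.shape[1])
    if n_comp < 1:
        raise ValueError("not enough cells/regions for PCA")
    scores = PCA(n_components=n_comp).fit_transform(table)
    plugin = plugin or _default_density_plugin
    labels = np.asarray(plugin(scores))
    if labels.shape != (len(table),):
        raise ValueError("density plugin must return one label per cell")
    return pd.factorize(labels)[0].astype(np.int64)
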