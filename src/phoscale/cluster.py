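"""Hierarchical clustering of log2 fold-change profiles.

Rows (events) are clustered on Euclidean distance with the
pairwise-complete convention for missing values: the squared distance over
the m mutually observed columns is scaled up by p/m (p = total columns)
before the square root.  Agglomeration follows the ward.D2 rule — the
Lance-Williams update applied to *squared* dissimilarities, with merge
heights reported as the square roots of the updated squared criterion.
Ties are broken deterministically by the smallest cluster index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics.pairwise import nan_euclidean_distances

from .errors import InputError


@dataclass
class Dendrogram:
    """Merge history in scipy linkage convention.

    ``merges[s] = (left, right, height, size)``: clusters ``left`` and
    ``right`` (original leaves are 0..n-1, the cluster formed at step s has
    id n+s) merged at the given height.
    """

    merges: np.ndarray  # (n-1, 4)
    n_leaves: int

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


def filter_min_observed(matrix: pd.DataFrame, min_observed: int = 2) -> tuple[pd.DataFrame, list]:
    """Drop rows with fewer than ``min_observed`` non-missing values;
    return the kept matrix and the list of excluded row keys."""
    n_obs = matrix.notna().sum(axis=1)
    excluded = list(matrix.index[n_obs < min_observed])
    return matrix.loc[n_obs >= min_observed], excluded


def euclidean_distance_na(matrix: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Pairwise-complete Euclidean distance matrix.

    d(x, y) = sqrt((p / m) * sum over mutually observed columns (x_j - y_j)^2)

    Raises :class:`InputError` if any row pair shares no observed column
    (callers should pre-filter with :func:`filter_min_observed`).
    """
    X = matrix.to_numpy(dtype=float) if isinstance(matrix, pd.DataFrame) else np.asarray(matrix, float)
    D = nan_euclidean_distances(X)
    if np.isnan(D).any():
        bad = [tuple(ij) for ij in np.argwhere(np.isnan(np.triu(D, 1)) & (np.triu(np.ones_like(D), 1) > 0))]
        raise InputError(f"row pairs with no mutually observed column: {bad[:10]}")
    D = 0.5 * (D + D.T)
    np.fill_diagonal(D, 0.0)
    return D


def ward_d2_linkage(D: np.ndarray) -> Dendrogram:
    """Agglomerate a distance matrix with the ward.D2 rule.

    Lance-Williams on squared dissimilarities:
        d2(k, i+j) = [(n_i + n_k) d2(k,i) + (n_j + n_k) d2(k,j)
                      - n_k d2(i,j)] / (n_i + n_j + n_k)
    Heights are sqrt of the merge criterion.  At every step the minimal
    entry is merged; ties go to the lexicographically smallest cluster-id
    pair.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise InputError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-12):
        raise InputError("distance matrix must be symmetric")
    if (D < 0).any() or not np.allclose(np.diag(D), 0.0):
        raise InputError("distance matrix must be non-negative with zero diagonal")
    if n < 2:
        raise InputError("need at least 2 rows to cluster")

    d2 = D.astype(float) ** 2
    active = list(range(n))  # cluster ids, in creation order
    sizes = {i: 1 for i in range(n)}
    # working squared-dissimilarity store keyed by unordered id pair
    store: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            store[(i, j)] = d2[i, j]

    def get(a: int, b: int) -> float:
        return store[(a, b) if a < b else (b, a)]

    merges = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                key = (a, b) if a < b else (b, a)
                val = store[key]
                if best is None or val < best[0] or (val == best[0] and key < best[1]):
                    best = (val, key)
        val, (i, j) = best
        ni, nj = sizes[i], sizes[j]
        new = next_id
        next_id += 1
        for k in active:
            if k in (i, j):
                continue
            nk = sizes[k]
            upd = ((ni + nk) * get(k, i) + (nj + nk) * get(k, j) - nk * val) / (ni + nj + nk)
            store[(k, new) if k < new else (new, k)] = upd
        active = [k for k in active if k not in (i, j)] + [new]
        sizes[new] = ni + nj
        merges[step] = (i, j, np.sqrt(max(val, 0.0)), ni + nj)
    return Dendrogram(merges=merges, n_leaves=n)


def cut_clusters(dendrogram: Dendrogram, k: int) -> np.ndarray:
    """Cut the tree into ``k`` groups.

    Applies the first n-k merges; labels are 1..k, numbered by the first
    leaf (smallest row index) appearing in each cluster.
    """
    n = dendrogram.n_leaves
    if not 1 <= k <= n:
        raise InputError(f"k must be in 1..{n}, got {k}")
    parent = list(range(2 * n - 1))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for step in range(n - k):
        i, j = int(dendrogram.merges[step, 0]), int(dendrogram.merges[step, 1])
        new = n + step
        parent[find(i)] = new
        parent[find(j)] = new

    roots = [find(i) for i in range(n)]
    label_of: dict[int, int] = {}
    labels = np.zeros(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in label_of:
            label_of[r] = len(label_of) + 1
        labels[i] = label_of[r]
    return labels


def check_monotone(dendrogram: Dendrogram, atol: float = 1e-9) -> bool:
    """Ward merge heights must be non-decreasing."""
    h = dendrogram.heights
    return bool(np.all(np.diff(h) >= -atol))


def linkage_frame(dendrogram: Dendrogram) -> pd.DataFrame:
    return pd.DataFrame(dendrogram.merges, columns=["left", "right", "height", "size"])
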