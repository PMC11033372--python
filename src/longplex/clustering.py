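"""Agglomerative hierarchical clustering: Euclidean distance, Ward.D2.

Ward.D2 operates on *unsquared* Euclidean distances, squaring inside
the Lance-Williams update:

    d(k, i+j)^2 = [ (n_i+n_k) d_ik^2 + (n_j+n_k) d_jk^2 - n_k d_ij^2 ]
                  / (n_i + n_j + n_k)

which for Euclidean input equals sqrt(2 |A||B| / (|A|+|B|)) times the
distance between cluster centroids. The implementation is a plain
greedy global-minimum agglomeration (O(n^3), ample for panel-sized
inputs) with a deterministic tie-break: among minimal-cost pairs, the
lowest (i, j) cluster-id pair merges first. Merge heights are
non-decreasing because the Ward criterion is reducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


@dataclass
class MergeTree:
    """Agglomeration record in scipy linkage convention.

    ``merges`` is an (n-1, 4) array: the two cluster ids merged (leaves
    are 0..n-1, the i-th merge creates id n+i), the merge height, and
    the size of the new cluster.
    """

    merges: np.ndarray
    labels: list[str]
    method: str = "ward.D2"
    metric: str = "euclidean"

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf order from recursive subtree traversal
        (no optimal-leaf reordering)."""
        n = self.n_leaves
        order: list[int] = []
        stack = [int(2 * n - 2)] if n > 1 else [0]
        while stack:
            node = stack.pop()
            if node < n:
                order.append(node)
            else:
                a, b = self.merges[node - n, 0], self.merges[node - n, 1]
                stack.append(int(b))
                stack.append(int(a))
        return order

    def ordered_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_order()]

    def to_linkage(self) -> np.ndarray:
        """The merge array as a scipy ``linkage`` matrix."""
        return self.merges.astype(float)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "metric": self.metric,
            "labels": self.labels,
            "merges": self.merges.tolist(),
            "leaf_order": self.leaf_order(),
        }


def pairwise_euclidean(matrix) -> tuple[np.ndarray, list]:
    """Euclidean distance matrix over rows.

    Rows containing missing values are dropped (logged); returns the
    symmetric zero-diagonal distance matrix and the kept row labels.
    """
    if isinstance(matrix, pd.DataFrame):
        values = matrix.to_numpy(dtype=float)
        labels = list(matrix.index)
    else:
        values = np.asarray(matrix, dtype=float)
        labels = list(range(values.shape[0]))
    keep = ~np.isnan(values).any(axis=1)
    if not keep.all():
        dropped = [labels[i] for i in np.flatnonzero(~keep)]
        logger.warning("dropping %d row(s) with missing values: %s", len(dropped), dropped)
        values = values[keep]
        labels = [l for l, k in zip(labels, keep) if k]
    if values.shape[0] < 2:
        raise ValueError("need at least 2 complete observations")
    return squareform(pdist(values, metric="euclidean")), labels


def ward2_linkage(d: np.ndarray, labels: list | None = None) -> MergeTree:
    """Ward.D2 agglomeration of a (unsquared) Euclidean distance matrix."""
    d = np.asarray(d, dtype=float)
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(d, d.T, rtol=1e-10, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    if labels is None:
        labels = [str(i) for i in range(n)]

    d2 = d.astype(float) ** 2  # work on squared distances
    active: dict[int, int] = {i: 1 for i in range(n)}  # cluster id -> size
    pos = {i: i for i in range(n)}  # cluster id -> row in working matrix
    work = d2.copy()
    np.fill_diagonal(work, np.inf)
    merges = np.zeros((n - 1, 4))

    for step in range(n - 1):
        ids = sorted(active)
        best = None
        for ai in range(len(ids)):
            for bi in range(ai + 1, len(ids)):
                i, j = ids[ai], ids[bi]
                cost = work[pos[i], pos[j]]
                # tie-break: lowest (i, j) id pair wins, strict < keeps it
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        ni, nj = active[i], active[j]
        new_id = n + step
        height = float(np.sqrt(cost))
        merges[step] = (i, j, height, ni + nj)

        # Lance-Williams update on squared distances
        pi, pj = pos[i], pos[j]
        for k in sorted(active):
            if k in (i, j):
                continue
            nk = active[k]
            pk = pos[k]
            new_d2 = ((ni + nk) * work[pi, pk] + (nj + nk) * work[pj, pk]
                      - nk * cost) / (ni + nj + nk)
            work[pi, pk] = work[pk, pi] = new_d2
        work[pj, :] = np.inf
        work[:, pj] = np.inf
        del active[i], active[j], pos[i], pos[j]
        active[new_id] = ni + nj
        pos[new_id] = pi

    return MergeTree(merges=merges, labels=[str(l) for l in labels])


def cluster_heatmap_export(
    matrix: pd.DataFrame,
    axes: str = "both",
    zscore_rows: bool = False,
) -> dict:
    """Cluster rows/columns and return the leaf-ordered matrix.

    ``axes`` is one of {"samples", "analytes", "both"}; rows are
    samples. With ``zscore_rows`` the exported matrix is per-row
    standardized for display (the trees are always built on the input
    values). Returns dict with keys ``matrix``, ``row_tree``,
    ``col_tree`` (trees None for unclustered axes).
    """
    if axes not in {"samples", "analytes", "both"}:
        raise ValueError(f"unknown axes: {axes!r}")
    out = matrix.copy()
    row_tree = col_tree = None
    if axes in {"samples", "both"}:
        d, labels = pairwise_euclidean(out)
        row_tree = ward2_linkage(d, labels=labels)
        out = out.loc[row_tree.ordered_labels()]
    if axes in {"analytes", "both"}:
        d, labels = pairwise_euclidean(out.T)
        col_tree = ward2_linkage(d, labels=labels)
        out = out[col_tree.ordered_labels()]
    if zscore_rows:
        vals = out.to_numpy(dtype=float)
        mu = np.nanmean(vals, axis=1, keepdims=True)
        sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
        sd[sd == 0] = np.nan
        out.loc[:, :] = (vals - mu) / sd
    return {"matrix": out, "row_tree": row_tree, "col_tree": col_tree}
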