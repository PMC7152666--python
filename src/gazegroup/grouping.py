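"""Agglomerative hierarchical clustering of participants and metrics.

A deliberately direct O(p³) agglomeration is used (participant counts in
eye-tracking studies are tens, not thousands), which lets ties be broken
by smallest cluster index so every run is fully deterministic. Linkages:
average (UPGMA, default), single, complete.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

_LINKAGES = ("average", "single", "complete")


@dataclass
class Dendrogram:
    """Merge tree of agglomerative clustering.

    ``merges`` has one row per merge: (cluster_a, cluster_b, height, size),
    where leaves are 0..p−1 and merge t creates cluster p+t (same id scheme
    as scipy). ``labels`` maps leaf indices to item ids.
    """

    merges: np.ndarray  # (p-1, 4)
    labels: list[str]
    method: str

    @property
    def p(self) -> int:
        return len(self.labels)

    def leaf_order(self) -> list[int]:
        """Left-to-right leaf indices; children ordered smallest-leaf-first."""
        p = self.p
        children: dict[int, tuple[int, int]] = {}
        for t, (a, b, _, _) in enumerate(self.merges):
            children[p + t] = (int(a), int(b))

        min_leaf: dict[int, int] = {i: i for i in range(p)}
        for node in sorted(children):
            a, b = children[node]
            min_leaf[node] = min(min_leaf[a], min_leaf[b])

        root = p + len(self.merges) - 1 if len(self.merges) else 0
        order: list[int] = []
        stack = [root]
        while stack:
            node = stack.pop()
            if node < p:
                order.append(node)
            else:
                a, b = children[node]
                first, second = (a, b) if min_leaf[a] <= min_leaf[b] else (b, a)
                stack.append(second)
                stack.append(first)
        return order

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "method": self.method,
            "merges": [
                {"a": int(a), "b": int(b), "height": float(h), "size": int(s)}
                for a, b, h, s in self.merges
            ],
            "leaf_order": self.leaf_order(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Dendrogram":
        merges = np.array(
            [[m["a"], m["b"], m["height"], m["size"]] for m in d["merges"]], dtype=float
        ).reshape(-1, 4)
        return cls(merges=merges, labels=list(d["labels"]), method=d["method"])


def _validate_matrix(dist: np.ndarray) -> np.ndarray:
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(dist) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if np.any(dist < 0):
        raise ValueError("distances must be non-negative")
    return dist


def linkage(
    dissimilarity: np.ndarray | pd.DataFrame,
    method: str = "average",
    labels: list[str] | None = None,
) -> Dendrogram:
    """Agglomerate a symmetric zero-diagonal dissimilarity matrix.

    Ties in the minimum inter-cluster distance are broken by the smallest
    (then second-smallest) cluster index, making the merge order — not just
    the heights — deterministic.
    """
    if method not in _LINKAGES:
        raise ValueError(f"unknown linkage {method!r}; choose from {_LINKAGES}")
    if isinstance(dissimilarity, pd.DataFrame):
        if labels is None:
            labels = [str(i) for i in dissimilarity.index]
        dissimilarity = dissimilarity.to_numpy(dtype=float)
    dist = _validate_matrix(dissimilarity)
    p = dist.shape[0]
    if labels is None:
        labels = [str(i) for i in range(p)]
    if p < 2:
        return Dendrogram(merges=np.empty((0, 4)), labels=labels, method=method)

    # inter-cluster distances keyed by frozen pairs of active cluster ids
    d: dict[tuple[int, int], float] = {}
    for i in range(p):
        for j in range(i + 1, p):
            d[(i, j)] = dist[i, j]
    size = {i: 1 for i in range(p)}
    active = set(range(p))
    merges = np.zeros((p - 1, 4))

    for t in range(p - 1):
        best = min(d.items(), key=lambda kv: (kv[1], kv[0]))
        (a, b), height = best
        new = p + t
        merges[t] = (a, b, height, size[a] + size[b])
        active.discard(a)
        active.discard(b)
        for c in sorted(active):
            dac = d.pop((min(a, c), max(a, c)))
            dbc = d.pop((min(b, c), max(b, c)))
            if method == "average":
                val = (size[a] * dac + size[b] * dbc) / (size[a] + size[b])
            elif method == "single":
                val = min(dac, dbc)
            else:
                val = max(dac, dbc)
            d[(c, new)] = val
        del d[(a, b)]
        size[new] = size[a] + size[b]
        active.add(new)

    return Dendrogram(merges=merges, labels=labels, method=method)


def cut(dendrogram: Dendrogram, k: int | None = None, height: float | None = None) -> dict[str, int]:
    """Cut the merge tree into flat groups.

    Exactly one of ``k`` (number of groups) or ``height`` (apply merges up
    to and including that height) must be given. Group labels are 0..g−1 in
    leaf order, so increasing k refines the partition.
    """
    if (k is None) == (height is None):
        raise ValueError("specify exactly one of k or height")
    p = dendrogram.p
    if k is not None:
        if not 1 <= k <= p:
            raise ValueError(f"k must be in [1, {p}], got {k}")
        n_merges = p - k
    else:
        n_merges = int(np.sum(dendrogram.merges[:, 2] <= height))

    parent = list(range(p + n_merges))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in range(n_merges):
        a, b = int(dendrogram.merges[t, 0]), int(dendrogram.merges[t, 1])
        parent[find(a)] = p + t
        parent[find(b)] = p + t

    # number groups by first appearance along the dendrogram leaf order
    order = dendrogram.leaf_order()
    group_of_root: dict[int, int] = {}
    out: dict[str, int] = {}
    for leaf in order:
        root = find(leaf)
        if root not in group_of_root:
            group_of_root[root] = len(group_of_root)
        out[dendrogram.labels[leaf]] = group_of_root[root]
    return out


def participant_order(dendrogram: Dendrogram) -> list[str]:
    """Participant ids in dendrogram leaf order (for matrix reordering)."""
    return [dendrogram.labels[i] for i in dendrogram.leaf_order()]


def metric_order(
    correlation: pd.DataFrame, method: str = "average", absolute: bool = True
) -> list[str]:
    """Order metrics by clustering their correlation structure.

    Correlations are converted to distances d = 1 − |r| (default), so both
    strongly correlated and strongly anti-correlated — equally redundant —
    metric pairs end up adjacent; ``absolute=False`` uses d = 1 − r.
    """
    r = correlation.to_numpy(dtype=float)
    d = 1.0 - (np.abs(r) if absolute else r)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    dend = linkage(d, method=method, labels=[str(c) for c in correlation.columns])
    return participant_order(dend)


def threshold_split(
    table: pd.DataFrame, column: str | pd.Series, threshold: float
) -> dict[str, int]:
    """Two-group split: group 0 has value > threshold, group 1 has value ≤ it."""
    col = table[column] if isinstance(column, str) else column
    return {str(i): (0 if v > threshold else 1) for i, v in col.items()}


def group_sizes(assignment: Mapping[str, int]) -> dict[int, int]:
    sizes: dict[int, int] = {}
    for g in assignment.values():
        sizes[g] = sizes.get(g, 0) + 1
    return sizes
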