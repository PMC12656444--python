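"""Hierarchical clustering of normalized trait profiles.

Group-mean profiles (condition x timepoint x species combinations over the
direction-harmonized, min–max scaled traits) are clustered agglomeratively
with Euclidean distance and complete linkage — the construction behind
trait/treatment heatmap dendrograms. Complete linkage defines the distance
between clusters as the maximum pairwise member distance, which guarantees
monotone non-decreasing merge heights.

Merges are bit-for-bit reproducible: when two candidate merges tie in
height, the pair containing the lowest original leaf index wins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LinkageTree",
    "euclidean_distance_matrix",
    "complete_linkage",
    "cut_tree",
    "group_mean_matrix",
]


def group_mean_matrix(m) -> pd.DataFrame:
    """Collapse a NormalizedMatrix to group means: one row per
    (species, condition, timepoint) treatment combination."""
    return m.data.groupby(level=["species", "condition", "timepoint"]).mean()


def euclidean_distance_matrix(
    data, axis: str = "rows"
) -> tuple[list[str], np.ndarray]:
    """Pairwise Euclidean distances between rows (or columns) of a matrix.

    ``data`` is a DataFrame or a NormalizedMatrix. Missing entries are
    handled pairwise-complete: the squared distance over the m commonly
    observed coordinates is rescaled by p/m (p coordinates total) so that
    distances remain comparable across pairs with different coverage. A pair
    with no common coordinate is an error.

    Returns ``(labels, D)`` with D symmetric, zero-diagonal, non-negative.
    """
    if hasattr(data, "data"):  # NormalizedMatrix
        data = data.data
    if axis == "columns":
        data = data.T
    elif axis != "rows":
        raise ValueError("axis must be 'rows' or 'columns'")
    X = data.to_numpy(dtype=float)
    labels = ["|".join(map(str, i)) if isinstance(i, tuple) else str(i) for i in data.index]
    n, p = X.shape
    if n < 2:
        raise ValueError("need >= 2 vectors to compute distances")
    D = np.zeros((n, n))
    obs = np.isfinite(X)
    for i in range(n):
        for j in range(i + 1, n):
            both = obs[i] & obs[j]
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"vectors {labels[i]!r} and {labels[j]!r} share no observed coordinate"
                )
            d2 = float(np.sum((X[i, both] - X[j, both]) ** 2)) * (p / m)
            D[i, j] = D[j, i] = np.sqrt(d2)
    return labels, D


@dataclass(frozen=True)
class LinkageTree:
    """Agglomerative merge history.

    Leaves are numbered 0..n-1 in input order; merge step k creates internal
    node n+k. ``merges`` lists (node_a, node_b, height, size) in merge order.
    """

    merges: tuple[tuple[int, int, float, int], ...]
    labels: tuple[str, ...]

    @property
    def n_leaves(self) -> int:
        return len(self.labels)

    def heights(self) -> list[float]:
        return [m[2] for m in self.merges]

    def to_scipy(self) -> np.ndarray:
        """Linkage matrix in the conventional (n-1, 4) layout."""
        return np.array([[a, b, h, s] for a, b, h, s in self.merges], dtype=float)

    def leaf_sets(self) -> dict[int, frozenset[int]]:
        """Map every node id to the set of leaf indices below it."""
        sets: dict[int, frozenset[int]] = {
            i: frozenset([i]) for i in range(self.n_leaves)
        }
        for k, (a, b, _, _) in enumerate(self.merges):
            sets[self.n_leaves + k] = sets[a] | sets[b]
        return sets

    def to_newick(self) -> str:
        """Newick string with branch lengths = parent height - child height."""
        heights = {i: 0.0 for i in range(self.n_leaves)}
        children: dict[int, tuple[int, int]] = {}
        for k, (a, b, h, _) in enumerate(self.merges):
            node = self.n_leaves + k
            heights[node] = h
            children[node] = (a, b)
        root = self.n_leaves + len(self.merges) - 1

        def render(node: int, parent_h: float) -> str:
            blen = parent_h - heights[node]
            if node < self.n_leaves:
                name = self.labels[node].replace(" ", "_").replace(",", "_")
                return f"{name}:{blen:.12g}"
            a, b = children[node]
            h = heights[node]
            return f"({render(a, h)},{render(b, h)}):{blen:.12g}"

        a, b = children[root]
        h = heights[root]
        return f"({render(a, h)},{render(b, h)});"


def complete_linkage(
    dist: np.ndarray, labels: Sequence[str] | None = None
) -> LinkageTree:
    """Agglomerative clustering with complete (maximum) linkage.

    At each step the pair of clusters with the smallest maximum inter-member
    distance is merged; ties go to the pair containing the lowest original
    leaf index (then the lowest on the other side), so output is
    deterministic.
    """
    D = np.asarray(dist, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape != (n, n):
        raise ValueError("dist must be a square matrix")
    if n < 2:
        raise ValueError("need >= 2 leaves")
    if not np.all(np.isfinite(D)):
        raise ValueError("dist contains non-finite entries")
    if not np.allclose(D, D.T) or not np.allclose(np.diag(D), 0):
        raise ValueError("dist must be symmetric with zero diagonal")
    if labels is None:
        labels = [str(i) for i in range(n)]
    labels = tuple(labels)
    if len(labels) != n:
        raise ValueError("labels length mismatch")

    # active cluster id -> (min original leaf, member leaves)
    members: dict[int, frozenset[int]] = {i: frozenset([i]) for i in range(n)}
    cdist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[int, int, float, int]] = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for (i, j), d in cdist.items():
            key = (d, min(min(members[i]), min(members[j])),
                   max(min(members[i]), min(members[j])))
            if best is None or key < best[0]:
                best = (key, (i, j))
        (h, _, _), (i, j) = best
        new_set = members[i] | members[j]
        a, b = (i, j) if i < j else (j, i)
        merges.append((a, b, h, len(new_set)))
        # complete linkage update: d(new, k) = max(d(i,k), d(j,k))
        others = [k for k in members if k not in (i, j)]
        for k in others:
            dik = cdist[(min(i, k), max(i, k))]
            djk = cdist[(min(j, k), max(j, k))]
            cdist[(min(next_id, k), max(next_id, k))] = max(dik, djk)
        for pair in list(cdist):
            if i in pair or j in pair:
                del cdist[pair]
        del members[i], members[j]
        members[next_id] = new_set
        next_id += 1
    return LinkageTree(merges=tuple(merges), labels=labels)


def cut_tree(tree: LinkageTree, k: int) -> dict[str, int]:
    """Cut into ``k`` flat clusters by undoing the k-1 highest merges.

    Returns leaf label -> cluster id; ids are numbered by each cluster's
    lowest leaf index in input order (0-based, ascending).
    """
    n = tree.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    sets = tree.leaf_sets()
    for a, b, _, _ in tree.merges[: n - k]:
        ra = find(min(sets[a]))
        rb = find(min(sets[b]))
        parent[max(ra, rb)] = min(ra, rb)
    roots = sorted({find(i) for i in range(n)})
    cluster_id = {root: idx for idx, root in enumerate(roots)}
    return {tree.labels[i]: cluster_id[find(i)] for i in range(n)}
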