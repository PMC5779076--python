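"""Linkage analysis: drug similarity dendrograms and risk-ordered leaves.

Drugs are clustered agglomeratively on the Euclidean distance between their
(usually normalised) metric vectors.  The binary merge tree can then be
rotated — every internal node may swap its children without changing the
branching structure — to order the leaves as close as possible to ascending
risk category (category 2 = highest risk first is "descending risk").  The
quality of an ordering is the mean squared difference between the leaf
categories read left to right and the ideal sorted sequence
(2,2,...,3,3,...,4,...,5):

    R = (1/N) * sum_i (a_i - o_i)^2

The optimal rotation is found exactly by dynamic programming over subtrees
(equivalent to enumerating all 2^(internal nodes) rotations).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

LINKAGE_METHODS = ("single", "complete", "average", "ward")


@dataclass
class Dendrogram:
    """A SciPy linkage matrix plus the leaf (drug) names it refers to."""

    linkage_matrix: np.ndarray
    leaves: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def heights(self) -> np.ndarray:
        """Merge heights, non-decreasing for the supported linkages."""
        return self.linkage_matrix[:, 2].copy()

    def to_newick(self) -> str:
        """Newick string with drug names as leaf labels and merge-height
        differences as branch lengths."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage_matrix, list(self.leaves))
        return str(tree).strip()


def build_dendrogram(table: pd.DataFrame, method: str = "average") -> Dendrogram:
    """Agglomerative clustering of drugs on Euclidean metric distance.

    ``table`` is drugs x metrics; all used cells must be present.  The
    default linkage is average (UPGMA); single/complete/ward are accepted.
    """
    if method not in LINKAGE_METHODS:
        raise ValueError(f"method must be one of {LINKAGE_METHODS}")
    if len(table) < 2:
        raise ValueError("need at least two drugs to cluster")
    missing = [
        f"({row}, {col})"
        for row in table.index
        for col in table.columns
        if pd.isna(table.loc[row, col])
    ]
    if missing:
        raise ValueError("missing metric values: " + ", ".join(missing))
    Z = hierarchy.linkage(table.to_numpy(dtype=float), method=method, metric="euclidean")
    return Dendrogram(Z, [str(i) for i in table.index])


def ranking_error(leaf_categories, normalize: bool = True) -> float:
    """Squared deviation of a category sequence from its sorted ideal.

    ``leaf_categories`` is the risk category of each leaf read in dendrogram
    order; the ideal is the same multiset sorted ascending.  Returns the
    mean (divide by N) by default, or the raw sum with ``normalize=False``.
    """
    cats = np.asarray(leaf_categories, dtype=float)
    if cats.size == 0:
        raise ValueError("empty category sequence")
    ideal = np.sort(cats)
    total = float(np.sum((cats - ideal) ** 2))
    return total / cats.size if normalize else total


def optimal_leaf_order(dendrogram: Dendrogram, labels: pd.Series) -> list[str]:
    """Leaf ordering minimising :func:`ranking_error` via subtree rotations.

    Every leaf must have a category in ``labels``.  Exact dynamic
    programme: the cost of placing a subtree at a given start position
    decomposes over its children, so the optimum over all 2^(internal
    nodes) rotations is found in O(n^2).
    """
    cats = {}
    for name in dendrogram.leaves:
        if name not in labels.index or pd.isna(labels.loc[name]):
            raise ValueError(f"leaf {name!r} has no risk category")
        cats[name] = float(labels.loc[name])
    ideal = np.sort(np.array(list(cats.values())))

    root = hierarchy.to_tree(dendrogram.linkage_matrix)
    leaf_name = dendrogram.leaves

    @lru_cache(maxsize=None)
    def best(node_id: int, start: int):
        node = _node_index[node_id]
        if node.is_leaf():
            c = cats[leaf_name[node.id]]
            return (c - ideal[start]) ** 2, (leaf_name[node.id],)
        left, right = node.left, node.right
        cost_lr = best(left.id, start)[0] + best(right.id, start + left.get_count())[0]
        cost_rl = best(right.id, start)[0] + best(left.id, start + right.get_count())[0]
        if cost_lr <= cost_rl:
            a = best(left.id, start)[1] + best(right.id, start + left.get_count())[1]
            return cost_lr, a
        a = best(right.id, start)[1] + best(left.id, start + right.get_count())[1]
        return cost_rl, a

    _node_index = {}

    def index_nodes(node):
        _node_index[node.id] = node
        if not node.is_leaf():
            index_nodes(node.left)
            index_nodes(node.right)

    index_nodes(root)
    _, ordering = best(root.id, 0)
    best.cache_clear()
    return list(ordering)


def leaf_order_categories(ordering, labels: pd.Series) -> np.ndarray:
    return np.array([float(labels.loc[name]) for name in ordering])
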