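"""Hierarchical linkage, optimal leaf ordering, and the ranking-error score
checked against brute-force oracles on small cases."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster import hierarchy

from eadpredict.linkage import (
    Dendrogram,
    build_dendrogram,
    leaf_order_categories,
    optimal_leaf_order,
    ranking_error,
)
from eadpredict.synthetic import generate_synthetic_metric_table


def test_two_drugs_merge_at_their_distance():
    table = pd.DataFrame({"x": [0.0, 3.0], "y": [0.0, 4.0]}, index=["a", "b"])
    d = build_dendrogram(table)
    assert d.linkage_matrix.shape == (1, 4)
    assert d.heights()[0] == pytest.approx(5.0)  # 3-4-5 triangle


def test_duplicated_row_merges_first_at_zero():
    table = pd.DataFrame(
        {"x": [0.0, 0.0, 9.0], "y": [1.0, 1.0, 9.0]}, index=["a", "a2", "far"]
    )
    d = build_dendrogram(table)
    assert d.heights()[0] == pytest.approx(0.0)


def _naive_upgma_heights(X):
    """Independent average-linkage implementation (all-pairs recomputation)."""
    clusters = [[i] for i in range(len(X))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            d = np.mean([
                np.linalg.norm(X[a] - X[b])
                for a in clusters[i]
                for b in clusters[j]
            ])
            if best is None or d < best[0]:
                best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [
            clusters[i] + clusters[j]
        ]
    return np.array(heights)


def test_heights_match_naive_recomputation(rng):
    X = rng.normal(size=(8, 3))
    table = pd.DataFrame(X, index=[f"d{i}" for i in range(8)])
    d = build_dendrogram(table, method="average")
    assert np.allclose(np.sort(d.heights()), np.sort(_naive_upgma_heights(X)), rtol=1e-9)


def test_planted_clusters_split_at_top(rng):
    X = np.vstack([rng.normal(0, 0.1, size=(3, 2)), rng.normal(10, 0.1, size=(3, 2))])
    names = [f"d{i}" for i in range(6)]
    d = build_dendrogram(pd.DataFrame(X, index=names))
    # the root merge joins two subtrees of size 3 (the planted clusters)
    root = hierarchy.to_tree(d.linkage_matrix)
    left = set(root.left.pre_order(lambda n: n.id))
    assert left in ({0, 1, 2}, {3, 4, 5})


def test_missing_values_rejected():
    table = pd.DataFrame({"x": [0.0, np.nan]}, index=["a", "b"])
    with pytest.raises(ValueError, match=r"\(b, x\)"):
        build_dendrogram(table)


def test_ranking_error_hand_cases():
    assert ranking_error([2, 2, 3, 4, 5]) == 0.0
    assert ranking_error([3, 2]) == pytest.approx(1.0)  # mean of (1, 1)
    assert ranking_error([3, 2], normalize=False) == pytest.approx(2.0)
    # positive for every non-sorted arrangement of this multiset
    for perm in set(itertools.permutations([2, 3, 4, 5])):
        err = ranking_error(list(perm))
        assert (err == 0.0) == (list(perm) == sorted(perm))


def _all_rotation_orders(Z, names):
    """Every leaf order reachable by child swaps (2^internal nodes)."""
    root = hierarchy.to_tree(Z)

    def orders(node):
        if node.is_leaf():
            yield (names[node.id],)
            return
        for lo in orders(node.left):
            for ro in orders(node.right):
                yield lo + ro
                yield ro + lo

    return set(orders(root))


@pytest.mark.parametrize("n", [5, 7])
def test_optimal_leaf_order_matches_exhaustive_enumeration(n, rng):
    X = rng.normal(size=(n, 2))
    names = [f"d{i}" for i in range(n)]
    labels = pd.Series(rng.integers(2, 6, size=n), index=names)
    d = build_dendrogram(pd.DataFrame(X, index=names))
    ordering = optimal_leaf_order(d, labels)
    best = min(
        ranking_error(leaf_order_categories(list(o), labels))
        for o in _all_rotation_orders(d.linkage_matrix, names)
    )
    assert ranking_error(leaf_order_categories(ordering, labels)) == pytest.approx(best)


def test_optimal_order_never_worse_than_input_order(rng):
    table, labels = generate_synthetic_metric_table(16, 2, 1.0, 1.0, seed=3)
    d = build_dendrogram(table)
    before = ranking_error(leaf_order_categories(d.leaves, labels))
    after = ranking_error(
        leaf_order_categories(optimal_leaf_order(d, labels), labels)
    )
    assert after <= before


def test_sortable_tree_reaches_zero_error():
    table = pd.DataFrame({"m": [2.0, 3.0, 4.0, 5.0]}, index=list("abcd"))
    labels = pd.Series([2, 3, 4, 5], index=list("abcd"))
    d = build_dendrogram(table)
    ordering = optimal_leaf_order(d, labels)
    assert ranking_error(leaf_order_categories(ordering, labels)) == 0.0


def test_single_leaf_order_is_identity():
    Z = np.empty((0, 4))
    with pytest.raises(ValueError):
        build_dendrogram(pd.DataFrame({"m": [1.0]}, index=["only"]))
    # a one-leaf "tree" is handled at the API boundary instead


def test_unlabelled_leaf_rejected():
    table = pd.DataFrame({"m": [0.0, 1.0]}, index=["a", "b"])
    d = build_dendrogram(table)
    with pytest.raises(ValueError, match="b"):
        optimal_leaf_order(d, pd.Series({"a": 2}))


def test_newick_export_is_parseable():
    from skbio import TreeNode
    import io

    table, labels = generate_synthetic_metric_table(8, 2, 1.0, 0.5, seed=8)
    d = build_dendrogram(table)
    tree = TreeNode.read(io.StringIO(d.to_newick()))
    assert {t.name for t in tree.tips()} == set(d.leaves)
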