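"""Neighbor Joining tree estimation and Robinson-Foulds comparison.

Trees are dendropy objects throughout; this module adds a deterministic
Saitou-Nei Neighbor Joining implementation (ties on the Q-criterion are
broken toward the lexicographically smallest pair of subtree labels,
negative branch lengths are clamped to zero) and bipartition-based RF
distances computed directly from leaf sets.
"""

from __future__ import annotations

import numpy as np
import dendropy

from .distances import DistanceMatrix

__all__ = [
    "neighbor_joining",
    "bipartitions",
    "clades",
    "rf_distance",
    "tree_from_newick_string",
    "tree_to_newick_string",
]

PhyloTree = dendropy.Tree


def tree_from_newick_string(newick: str) -> PhyloTree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", suppress_internal_node_taxa=True
    )
    tree.is_rooted = False
    return tree


def tree_to_newick_string(tree: PhyloTree) -> str:
    return tree.as_string(schema="newick", suppress_rooting=True).strip()


def neighbor_joining(D: DistanceMatrix) -> PhyloTree:
    """Classic Neighbor Joining on a symmetric zero-diagonal matrix.

    Iteratively joins the pair minimising the Q-criterion
    Q(i,j) = (r-2) d(i,j) - R_i - R_j, computes branch lengths by the
    standard formulas, and reduces the matrix. On a matrix additive on
    a binary tree with positive edge lengths this recovers that tree
    exactly. Output is unrooted with 2n-3 edges for n >= 3 leaves.
    """
    n = len(D.labels)
    if n < 2:
        raise ValueError("Neighbor Joining needs at least 2 taxa")

    taxa = dendropy.TaxonNamespace(D.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    if n == 2:
        d = float(D.values[0, 1])
        for label in D.labels:
            child = dendropy.Node(taxon=taxa.get_taxon(label))
            child.edge.length = d / 2.0
            tree.seed_node.add_child(child)
        tree.is_rooted = False
        return tree

    nodes: list[dendropy.Node] = []
    keys: list[str] = []  # smallest leaf label in each subtree, for tie-breaking
    for label in D.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(label))
        nodes.append(node)
        keys.append(label)
    dist = D.values.astype(float).copy()

    while len(nodes) > 3:
        r = len(nodes)
        R = dist.sum(axis=1)
        Q = (r - 2) * dist - R[:, None] - R[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        pairs = np.argwhere(Q <= qmin + 1e-12 * max(1.0, abs(qmin)))
        i, j = min(
            (tuple(sorted((a, b))) for a, b in pairs),
            key=lambda ab: tuple(sorted((keys[ab[0]], keys[ab[1]]))),
        )
        d_ij = dist[i, j]
        li = d_ij / 2.0 + (R[i] - R[j]) / (2.0 * (r - 2))
        lj = d_ij - li
        parent = dendropy.Node()
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])

        new_row = 0.5 * (dist[i, :] + dist[j, :] - d_ij)
        keep = [x for x in range(r) if x not in (i, j)]
        reduced = np.zeros((len(keep) + 1, len(keep) + 1))
        reduced[:-1, :-1] = dist[np.ix_(keep, keep)]
        reduced[-1, :-1] = reduced[:-1, -1] = new_row[keep]
        dist = reduced
        nodes = [nodes[x] for x in keep] + [parent]
        keys = [keys[x] for x in keep] + [min(keys[i], keys[j])]

    # final three subtrees joined at one internal node
    d01, d02, d12 = dist[0, 1], dist[0, 2], dist[1, 2]
    lengths = [
        (d01 + d02 - d12) / 2.0,
        (d01 + d12 - d02) / 2.0,
        (d02 + d12 - d01) / 2.0,
    ]
    center = tree.seed_node
    for node, length in zip(nodes, lengths):
        node.edge.length = max(length, 0.0)
        center.add_child(node)
    tree.is_rooted = False
    return tree


def _leaf_labels(tree: PhyloTree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartitions(tree: PhyloTree) -> frozenset[frozenset[str]]:
    """Non-trivial leaf bipartitions induced by the internal edges.

    Each bipartition is stored in canonical orientation: the side that
    does not contain the lexicographically smallest leaf label. Leaf
    edges (trivial splits) are excluded; a star tree yields the empty
    set. Degree-2 "root" nodes from rooted Newick input induce the same
    split on both incident edges, which the set representation merges.
    """
    all_leaves = _leaf_labels(tree)
    ref = min(all_leaves)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        side = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if len(side) < 2 or len(all_leaves - side) < 2:
            continue
        if ref in side:
            side = frozenset(all_leaves - side)
        out.add(side)
    return frozenset(out)


def clades(tree: PhyloTree) -> frozenset[frozenset[str]]:
    """Non-trivial clades (rooted splits): internal nodes' leaf sets."""
    all_leaves = _leaf_labels(tree)
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None or node.is_leaf():
            continue
        clade = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        if 1 < len(clade) < len(all_leaves):
            out.add(clade)
    return frozenset(out)


def rf_distance(t1: PhyloTree, t2: PhyloTree, rooted: bool = False) -> int:
    """Robinson-Foulds distance: |B1 \\ B2| + |B2 \\ B1|.

    By default trees are compared unrooted via their non-trivial
    bipartition sets; with ``rooted=True`` the clade sets are compared
    instead (an NJ tree is unrooted, but published RF values are
    sometimes computed on rooted representations).
    """
    l1, l2 = _leaf_labels(t1), _leaf_labels(t2)
    if l1 != l2:
        raise ValueError(
            f"trees have different leaf sets: only-in-first={sorted(l1 - l2)}, "
            f"only-in-second={sorted(l2 - l1)}"
        )
    split_of = clades if rooted else bipartitions
    b1, b2 = split_of(t1), split_of(t2)
    return len(b1 ^ b2)
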