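"""UPGMA tree reconstruction from a dissimilarity matrix.

Agglomerative average-linkage clustering: starting from singleton clusters,
each step merges the pair of clusters with the smallest size-weighted mean
inter-cluster dissimilarity

    J(u, v) = sum_{i in u, t in v} d(x_i, x_t) / (|u| |v|),

placing the new node at height min J / 2. The result is a rooted binary
ultrametric tree (all leaves equidistant from the root), serialized to
Newick with deterministic child ordering.

Ties in the minimal J are broken by the lexicographically smallest pair of
cluster name labels (each cluster named by its smallest leaf label), so the
merge sequence is reproducible across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signal_io import DissimilarityMatrix

__all__ = ["TreeNode", "Tree", "upgma", "to_newick", "is_cherry"]


@dataclass(frozen=True)
class TreeNode:
    """A node of a rooted ultrametric tree.

    Leaves carry a label and height 0; internal nodes carry the merge height
    (half the merge dissimilarity) and exactly two children. Branch length is
    parent height minus child height.
    """

    height: float
    label: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None

    def __post_init__(self) -> None:
        if (self.label is None) == (self.children is None):
            raise ValueError("a node is either a labelled leaf or has two children")

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaf_labels(self) -> tuple[str, ...]:
        if self.is_leaf:
            return (self.label,)  # type: ignore[return-value]
        left, right = self.children  # type: ignore[misc]
        return left.leaf_labels() + right.leaf_labels()


@dataclass(frozen=True)
class Tree:
    """A rooted binary ultrametric tree with unique leaf labels."""

    root: TreeNode
    merge_heights: tuple[float, ...] = field(default=(), repr=False)

    def __post_init__(self) -> None:
        labels = self.root.leaf_labels()
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")

    @property
    def leaves(self) -> tuple[str, ...]:
        return self.root.leaf_labels()

    def find_leaf_parent(self, label: str) -> TreeNode:
        """The internal node whose immediate child is the named leaf."""
        parent = _leaf_parent(self.root, label)
        if parent is None:
            raise KeyError(f"no leaf labelled {label!r}")
        return parent

    def newick(self) -> str:
        return to_newick(self)


def _leaf_parent(node: TreeNode, label: str) -> TreeNode | None:
    if node.is_leaf:
        return None
    for child in node.children:  # type: ignore[union-attr]
        if child.is_leaf and child.label == label:
            return node
    for child in node.children:  # type: ignore[union-attr]
        found = _leaf_parent(child, label)
        if found is not None:
            return found
    return None


def upgma(matrix: DissimilarityMatrix) -> Tree:
    """Build the UPGMA tree of a symmetric zero-diagonal dissimilarity matrix.

    After merging clusters u and v, the distance from the new cluster to any
    other cluster k is the size-weighted average
    (|u| d(u,k) + |v| d(v,k)) / (|u| + |v|), which keeps every entry equal to
    the mean pairwise leaf dissimilarity (true UPGMA, not WPGMA).
    """
    if matrix.n < 2:
        raise ValueError("need at least 2 leaves")
    # active clusters: name = smallest leaf label (for tie-breaking)
    nodes: list[TreeNode] = [TreeNode(0.0, label=l) for l in matrix.labels]
    names: list[str] = list(matrix.labels)
    sizes: list[int] = [1] * matrix.n
    D = matrix.values.astype(float).copy()
    heights: list[float] = []

    while len(nodes) > 1:
        best: tuple[str, str] | None = None
        best_ij: tuple[int, int] = (0, 1)
        best_d = np.inf
        for i in range(len(nodes)):
            for j in range(i + 1, len(nodes)):
                d = D[i, j]
                key = tuple(sorted((names[i], names[j])))
                if d < best_d or (d == best_d and (best is None or key < best)):
                    best_d, best, best_ij = d, key, (i, j)
        i, j = best_ij
        height = best_d / 2.0
        heights.append(height)
        # canonical child order: smaller cluster name first
        pair = sorted((i, j), key=lambda k: names[k])
        merged = TreeNode(height, children=(nodes[pair[0]], nodes[pair[1]]))
        si, sj = sizes[i], sizes[j]
        new_row = (si * D[i] + sj * D[j]) / (si + sj)
        keep = [k for k in range(len(nodes)) if k not in (i, j)]
        D = np.vstack([D[np.ix_(keep, keep)],
                       new_row[keep][None, :]])
        last = np.append(new_row[keep], 0.0)
        D = np.hstack([D, last[:, None]])
        nodes = [nodes[k] for k in keep] + [merged]
        names = [names[k] for k in keep] + [min(names[i], names[j])]
        sizes = [sizes[k] for k in keep] + [si + sj]

    return Tree(root=nodes[0], merge_heights=tuple(heights))


def _format_length(x: float) -> str:
    return format(x, ".12g")


def _newick_node(node: TreeNode, parent_height: float | None) -> str:
    if node.is_leaf:
        body = node.label
    else:
        # canonical order: lexicographically smallest descendant label first
        kids = sorted(node.children, key=lambda c: min(c.leaf_labels()))
        body = "(" + ",".join(_newick_node(c, node.height) for c in kids) + ")"
    if parent_height is None:
        return body
    return f"{body}:{_format_length(parent_height - node.height)}"


def to_newick(tree: Tree) -> str:
    """Serialize with branch lengths and deterministic child order."""
    return _newick_node(tree.root, None) + ";"


def is_cherry(tree: Tree, labelA: str, labelB: str) -> bool:
    """True iff the two named leaves share an immediate parent (2-leaf clade)."""
    for label in (labelA, labelB):
        if label not in tree.leaves:
            raise KeyError(f"no leaf labelled {label!r}")
    parent = tree.find_leaf_parent(labelA)
    kids = parent.children  # type: ignore[union-attr]
    return all(c.is_leaf for c in kids) and {c.label for c in kids} == {labelA, labelB}


def sibling_subtree_labels(tree: Tree, label: str) -> tuple[str, ...]:
    """Leaf labels of the subtree that is the named leaf's sibling.

    Used by the relaxed influence rule: the care-giver leaf "attaches next
    to" another signal when that signal sits anywhere in the sibling subtree.
    """
    parent = tree.find_leaf_parent(label)
    for child in parent.children:  # type: ignore[union-attr]
        if not (child.is_leaf and child.label == label):
            return child.leaf_labels()
    raise KeyError(f"no sibling found for leaf {label!r}")  # pragma: no cover
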