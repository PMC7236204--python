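"""Binary regression trees for the sum-of-trees sampler.

A tree is a recursive :class:`TreeNode`.  Internal nodes hold a split rule
(variable index, cutpoint index into that variable's grid); leaves hold a
real value ``mu``.  The split convention is fixed everywhere: values less
than or equal to the cutpoint go left, values greater go right.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "TreeNode",
    "make_cutpoint_grids",
    "evaluate",
    "partition",
    "leaves",
    "internal_nodes",
    "prunable_nodes",
    "node_depths",
    "clone",
    "tree_to_dict",
    "tree_from_dict",
]


class TreeNode:
    """A node of a binary regression tree.

    A leaf has ``var is None`` and carries ``mu``; an internal node has a
    split variable index ``var``, a cutpoint index ``cut``, and two children.
    """

    __slots__ = ("var", "cut", "left", "right", "mu")

    def __init__(self, var=None, cut=None, left=None, right=None, mu=0.0):
        self.var = var
        self.cut = cut
        self.left = left
        self.right = right
        self.mu = mu

    @property
    def is_leaf(self) -> bool:
        return self.var is None

    def __repr__(self):  # pragma: no cover - debugging aid
        if self.is_leaf:
            return f"Leaf(mu={self.mu:.4g})"
        return f"Split(x{self.var} <= cut[{self.cut}])"


def make_cutpoint_grids(X: np.ndarray, n_cutpoints: int) -> list[np.ndarray]:
    """Build the per-column cutpoint grids.

    Columns with few distinct values (dummies, small counts) get the
    midpoints between consecutive observed values — a 0/1 dummy gets the
    single cutpoint 0.5.  Columns with many distinct values get a uniform
    grid of ``n_cutpoints`` interior points over the observed range.
    Constant columns get an empty grid and are never split on.
    """
    grids = []
    for j in range(X.shape[1]):
        uniq = np.unique(X[:, j])
        if uniq.size <= 1:
            grids.append(np.empty(0))
        elif uniq.size - 1 <= n_cutpoints:
            grids.append((uniq[:-1] + uniq[1:]) / 2.0)
        else:
            lo, hi = uniq[0], uniq[-1]
            grids.append(np.linspace(lo, hi, n_cutpoints + 2)[1:-1])
    return grids


def evaluate(tree: TreeNode, X: np.ndarray, grids: list[np.ndarray]) -> np.ndarray:
    """Evaluate the tree function g(x; T) for every row of X."""
    out = np.empty(X.shape[0])
    stack = [(tree, np.arange(X.shape[0]))]
    while stack:
        node, idx = stack.pop()
        if node.is_leaf:
            out[idx] = node.mu
        else:
            cut = grids[node.var][node.cut]
            go_left = X[idx, node.var] <= cut
            stack.append((node.left, idx[go_left]))
            stack.append((node.right, idx[~go_left]))
    return out


def partition(tree: TreeNode, X: np.ndarray, grids: list[np.ndarray],
              idx: np.ndarray | None = None):
    """Assign rows to leaves.

    Returns parallel lists ``(leaf_nodes, row_index_arrays)`` covering all
    rows; the ordering of leaves is deterministic (left-to-right).
    """
    if idx is None:
        idx = np.arange(X.shape[0])
    leaf_nodes: list[TreeNode] = []
    row_sets: list[np.ndarray] = []
    stack = [(tree, idx)]
    while stack:
        node, rows = stack.pop()
        if node.is_leaf:
            leaf_nodes.append(node)
            row_sets.append(rows)
        else:
            cut = grids[node.var][node.cut]
            go_left = X[rows, node.var] <= cut
            stack.append((node.right, rows[~go_left]))
            stack.append((node.left, rows[go_left]))
    return leaf_nodes, row_sets


def leaves(tree: TreeNode) -> list[TreeNode]:
    out, stack = [], [tree]
    while stack:
        node = stack.pop()
        if node.is_leaf:
            out.append(node)
        else:
            stack.extend((node.right, node.left))
    return out


def internal_nodes(tree: TreeNode) -> list[TreeNode]:
    out, stack = [], [tree]
    while stack:
        node = stack.pop()
        if not node.is_leaf:
            out.append(node)
            stack.extend((node.right, node.left))
    return out


def prunable_nodes(tree: TreeNode) -> list[TreeNode]:
    """Internal nodes whose two children are both leaves."""
    return [n for n in internal_nodes(tree)
            if n.left.is_leaf and n.right.is_leaf]


def node_depths(tree: TreeNode) -> dict[int, int]:
    """Map id(node) -> depth for every node."""
    depths, stack = {}, [(tree, 0)]
    while stack:
        node, d = stack.pop()
        depths[id(node)] = d
        if not node.is_leaf:
            stack.append((node.left, d + 1))
            stack.append((node.right, d + 1))
    return depths


def clone(tree: TreeNode) -> TreeNode:
    if tree.is_leaf:
        return TreeNode(mu=tree.mu)
    return TreeNode(var=tree.var, cut=tree.cut,
                    left=clone(tree.left), right=clone(tree.right))


def tree_to_dict(tree: TreeNode) -> dict:
    if tree.is_leaf:
        return {"mu": float(tree.mu)}
    return {"var": int(tree.var), "cut": int(tree.cut),
            "left": tree_to_dict(tree.left), "right": tree_to_dict(tree.right)}


def tree_from_dict(d: dict) -> TreeNode:
    if "mu" in d:
        return TreeNode(mu=d["mu"])
    return TreeNode(var=d["var"], cut=d["cut"],
                    left=tree_from_dict(d["left"]),
                    right=tree_from_dict(d["right"]))
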