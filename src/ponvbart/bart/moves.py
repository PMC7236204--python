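"""Metropolis–Hastings structural moves for the backfitting sampler.

Each sweep proposes, per tree, one of four structural moves — grow, prune,
change, swap — and accepts or rejects it against the integrated-leaf
marginal likelihood of the current partial residual (unit residual
variance, conjugate normal leaf prior).  Leaf values are integrated out of
the acceptance ratio and redrawn afterwards from their conjugate
posteriors.
"""

from __future__ import annotations

import numpy as np

from .trees import (
    TreeNode,
    internal_nodes,
    leaves,
    node_depths,
    partition,
    prunable_nodes,
)

__all__ = ["tree_split_prior", "leaf_log_marginal", "tree_log_marginal",
           "propose_move", "draw_leaf_values"]

GROW, PRUNE, CHANGE, SWAP = 0, 1, 2, 3


def tree_split_prior(depth: int, alpha: float, beta: float) -> float:
    """Probability that a node at the given depth is internal: α(1+d)^(−β)."""
    return alpha * (1.0 + depth) ** (-beta)


def leaf_log_marginal(n: float, s: float, sigma_mu2: float) -> float:
    """Log marginal likelihood of a leaf's residuals, leaf value integrated out.

    Under r_i | mu ~ N(mu, 1) and mu ~ N(0, sigma_mu2), with n points summing
    to s; terms common to every partition of the same rows (the Gaussian
    normalizer and the residual sum of squares) are dropped, so this is valid
    only inside likelihood *ratios* between trees over the same rows.
    """
    v = 1.0 + n * sigma_mu2
    return -0.5 * np.log(v) + sigma_mu2 * s * s / (2.0 * v)


def _partition_stats(tree, X, grids, residual):
    """Leaf partition plus per-leaf (count, residual-sum) stats.

    Returns (leaf_nodes, row_sets, counts, sums) or None if some leaf is
    empty (such states are excluded by construction).
    """
    leaf_nodes, row_sets = partition(tree, X, grids)
    counts = np.array([rows.size for rows in row_sets], dtype=float)
    if np.any(counts == 0):
        return None
    sums = np.array([residual[rows].sum() for rows in row_sets])
    return leaf_nodes, row_sets, counts, sums


def tree_log_marginal(tree, X, grids, residual, sigma_mu2) -> float:
    """Sum of leaf log marginals over the tree's partition (−inf if a leaf is empty)."""
    stats = _partition_stats(tree, X, grids, residual)
    if stats is None:
        return -np.inf
    _, _, counts, sums = stats
    v = 1.0 + counts * sigma_mu2
    return float(np.sum(-0.5 * np.log(v) + sigma_mu2 * sums ** 2 / (2.0 * v)))


def _clone_with_map(tree):
    """Deep-copy the tree and return (copy, {id(original): copy_node})."""
    mapping = {}

    def rec(node):
        if node.is_leaf:
            new = TreeNode(mu=node.mu)
        else:
            new = TreeNode(var=node.var, cut=node.cut,
                           left=rec(node.left), right=rec(node.right))
        mapping[id(node)] = new
        return new

    return rec(tree), mapping


def _splittable_vars(grids):
    return [j for j, g in enumerate(grids) if g.size > 0]


def propose_move(tree, X, grids, residual, rng, *, move_probs, alpha, beta,
                 sigma_mu2):
    """Draw one structural move and its log MH acceptance ratio.

    Returns ``(candidate_tree, log_accept)``.  Degenerate draws (prune on a
    root-only tree, change/swap with no eligible node) return the identity
    candidate with log-acceptance 0.  Proposals creating an empty leaf get
    −inf.  The acceptance ratio combines the depth prior, the uniform split
    rule prior, the proposal ratio, and the integrated-leaf likelihood
    ratio; uniform rule-prior terms cancel against the rule-choice proposal
    terms for grow/prune and are symmetric for change/swap.
    """
    move = rng.choice(4, p=move_probs)
    cur_ml = tree_log_marginal(tree, X, grids, residual, sigma_mu2)

    if move == GROW:
        return _grow(tree, X, grids, residual, rng, move_probs, alpha, beta,
                     sigma_mu2, cur_ml)
    if move == PRUNE:
        return _prune(tree, X, grids, residual, rng, move_probs, alpha, beta,
                      sigma_mu2, cur_ml)
    if move == CHANGE:
        return _change(tree, X, grids, residual, rng, sigma_mu2, cur_ml)
    return _swap(tree, X, grids, residual, rng, sigma_mu2, cur_ml)


def _grow(tree, X, grids, residual, rng, move_probs, alpha, beta, sigma_mu2,
          cur_ml):
    svars = _splittable_vars(grids)
    if not svars:
        return tree, 0.0
    leaf_list = leaves(tree)
    target = leaf_list[rng.integers(len(leaf_list))]
    var = svars[rng.integers(len(svars))]
    cut = int(rng.integers(grids[var].size))

    cand, mapping = _clone_with_map(tree)
    node = mapping[id(target)]
    node.var, node.cut = var, cut
    node.left, node.right = TreeNode(mu=0.0), TreeNode(mu=0.0)
    node.mu = 0.0

    cand_ml = tree_log_marginal(cand, X, grids, residual, sigma_mu2)
    if not np.isfinite(cand_ml):
        return cand, -np.inf

    d = node_depths(tree)[id(target)]
    p_d = tree_split_prior(d, alpha, beta)
    p_child = tree_split_prior(d + 1, alpha, beta)
    log_prior = np.log(p_d) + 2.0 * np.log1p(-p_child) - np.log1p(-p_d)
    # reverse: prune picks this node among prunables of the candidate;
    # forward: grow picks this leaf (rule-choice terms cancel the rule prior)
    log_prop = (np.log(move_probs[PRUNE]) - np.log(len(prunable_nodes(cand)))
                - np.log(move_probs[GROW]) + np.log(len(leaf_list)))
    return cand, cand_ml - cur_ml + log_prior + log_prop


def _prune(tree, X, grids, residual, rng, move_probs, alpha, beta, sigma_mu2,
           cur_ml):
    prunable = prunable_nodes(tree)
    if not prunable:
        return tree, 0.0
    target = prunable[rng.integers(len(prunable))]

    cand, mapping = _clone_with_map(tree)
    node = mapping[id(target)]
    node.var = node.cut = node.left = node.right = None
    node.mu = 0.0

    cand_ml = tree_log_marginal(cand, X, grids, residual, sigma_mu2)
    d = node_depths(tree)[id(target)]
    p_d = tree_split_prior(d, alpha, beta)
    p_child = tree_split_prior(d + 1, alpha, beta)
    log_prior = np.log1p(-p_d) - np.log(p_d) - 2.0 * np.log1p(-p_child)
    log_prop = (np.log(move_probs[GROW]) - np.log(len(leaves(cand)))
                - np.log(move_probs[PRUNE]) + np.log(len(prunable)))
    return cand, cand_ml - cur_ml + log_prior + log_prop


def _change(tree, X, grids, residual, rng, sigma_mu2, cur_ml):
    nodes = internal_nodes(tree)
    if not nodes:
        return tree, 0.0
    target = nodes[rng.integers(len(nodes))]
    svars = _splittable_vars(grids)
    var = svars[rng.integers(len(svars))]
    cut = int(rng.integers(grids[var].size))

    cand, mapping = _clone_with_map(tree)
    node = mapping[id(target)]
    node.var, node.cut = var, cut
    cand_ml = tree_log_marginal(cand, X, grids, residual, sigma_mu2)
    if not np.isfinite(cand_ml):
        return cand, -np.inf
    return cand, cand_ml - cur_ml  # symmetric proposal, uniform rule prior


def _swap(tree, X, grids, residual, rng, sigma_mu2, cur_ml):
    pairs = [(p, c) for p in internal_nodes(tree)
             for c in (p.left, p.right) if not c.is_leaf]
    if not pairs:
        return tree, 0.0
    parent, child = pairs[rng.integers(len(pairs))]

    cand, mapping = _clone_with_map(tree)
    cp, cc = mapping[id(parent)], mapping[id(child)]
    cp.var, cp.cut, cc.var, cc.cut = cc.var, cc.cut, cp.var, cp.cut
    cand_ml = tree_log_marginal(cand, X, grids, residual, sigma_mu2)
    if not np.isfinite(cand_ml):
        return cand, -np.inf
    return cand, cand_ml - cur_ml  # symmetric; pair count unchanged by a swap


def draw_leaf_values(tree, X, grids, residual, sigma_mu2, rng):
    """Redraw every leaf value from its conjugate normal posterior.

    With n residuals summing to s in a leaf: mu | r ~ N(sigma_mu2*s/v,
    sigma_mu2/v), v = 1 + n*sigma_mu2.  Returns the per-row fitted vector.
    Every leaf is guaranteed nonempty by the move acceptance rule.
    """
    leaf_nodes, row_sets = partition(tree, X, grids)
    fit = np.empty(X.shape[0])
    for node, rows in zip(leaf_nodes, row_sets):
        if rows.size == 0:
            raise AssertionError("empty leaf reached the conjugate draw")
        v = 1.0 + rows.size * sigma_mu2
        mean = sigma_mu2 * residual[rows].sum() / v
        node.mu = mean + np.sqrt(sigma_mu2 / v) * rng.standard_normal()
        fit[rows] = node.mu
    return fit
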