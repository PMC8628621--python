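"""Structural tree operations: pruning, path lengths, random tree simulation.

Pruning keeps every retained tip's root-to-tip path length unchanged:
branch lengths of edges merged while suppressing unifurcations are summed,
and when a chain of single-child nodes above the root is collapsed, the
accumulated length is kept as the new root's own edge length (so total tree
depth is conserved). ``path_length_to_root`` therefore includes the root's
own edge length when one is present.
"""

from __future__ import annotations

from collections.abc import Iterable

import dendropy
import numpy as np

from .errors import PruneError, TreeValidationError
from .newick import Phylogeny

__all__ = [
    "prune_to",
    "path_length_to_root",
    "simulate_tree",
    "tree_signature",
    "trees_equal",
]


def prune_to(tree: Phylogeny, keep: Iterable[str]) -> Phylogeny:
    """Prune ``tree`` down to exactly the tips in ``keep``.

    Internal nodes left with a single child (including chains above the
    root) are suppressed with their branch lengths summed, so every retained
    tip's root-to-tip path length is unchanged. Relative tip order is
    preserved. The input tree is not modified.

    Raises
    ------
    PruneError
        If ``keep`` names an unknown tip or fewer than 2 tips would remain.
    """
    keep = set(keep)
    tips = tree.tip_set
    unknown = keep - tips
    if unknown:
        raise PruneError(f"unknown tip label(s): {sorted(unknown)}")
    if len(keep) < 2:
        raise PruneError(f"cannot reduce tree below 2 tips (asked to keep {len(keep)})")
    if keep == tips:
        return tree.copy()
    return Phylogeny(_rebuild_pruned(tree.dendropy_tree, keep))


def _merge_lengths(a: float | None, b: float | None) -> float | None:
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _rebuild_pruned(source: dendropy.Tree, keep: set[str]) -> dendropy.Tree:
    """Single postorder pass building the pruned tree: unifurcations are
    merged with edge lengths summed, a collapsed chain above the root
    survives as the new root's own edge length, and child order (hence tip
    order) is preserved."""
    namespace = dendropy.TaxonNamespace()
    rep: dict[dendropy.Node, dendropy.Node] = {}
    for node in source.postorder_node_iter():
        if node.is_leaf():
            if node.taxon.label in keep:
                new = dendropy.Node()
                new.taxon = namespace.new_taxon(node.taxon.label)
                new.edge.length = node.edge.length
                rep[node] = new
            continue
        kids = [rep[c] for c in node.child_nodes() if c in rep]
        if not kids:
            continue
        if len(kids) == 1:
            survivor = kids[0]
            survivor.edge.length = _merge_lengths(survivor.edge.length, node.edge.length)
            rep[node] = survivor
        else:
            new = dendropy.Node()
            new.edge.length = node.edge.length
            new.label = node.label
            for kid in kids:
                new.add_child(kid)
            rep[node] = new
    pruned = dendropy.Tree(taxon_namespace=namespace)
    pruned.seed_node = rep[source.seed_node]
    return pruned


def path_length_to_root(tree: Phylogeny, tip: str) -> float:
    """Sum of branch lengths from ``tip`` up to (and including any edge on)
    the root.

    Raises
    ------
    TreeValidationError
        If ``tip`` is not in the tree or an edge on the path lacks a length.
    """
    node = None
    for leaf in tree.dendropy_tree.leaf_node_iter():
        if leaf.taxon.label == tip:
            node = leaf
            break
    if node is None:
        raise TreeValidationError(f"unknown tip label: {tip!r}")
    total = 0.0
    while node is not None:
        length = node.edge.length
        if length is None and node.parent_node is not None:
            raise TreeValidationError(
                f"missing branch length on the path from {tip!r} to the root"
            )
        if length is not None:
            total += length
        node = node.parent_node
    return total


def simulate_tree(n_tips: int, seed: int | np.random.Generator) -> Phylogeny:
    """Simulate a random binary tree with ``n_tips`` labeled tips.

    The topology is built by recursive uniform random bipartition of the tip
    set (each left-subtree size drawn uniformly from 1..size-1), labels
    "t1".."t{n}" are assigned in random order, and branch lengths are i.i.d.
    uniform on (0, 1). The same ``(n_tips, seed)`` always yields the same
    tree. This mirrors the contract of the classic ``rtree`` simulator
    (random topology, uniform branch lengths, n labeled tips) without
    claiming distributional identity with it.
    """
    if n_tips < 2:
        raise TreeValidationError(f"cannot simulate a tree with {n_tips} < 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    labels = [f"t{i + 1}" for i in range(n_tips)]
    order = rng.permutation(n_tips)

    taxon_ns = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    # Iterative construction: an explicit stack avoids recursion limits on
    # unbalanced topologies at large n. Children are attached left-to-right.
    stack: list[tuple[dendropy.Node, int, int]] = [(tree.seed_node, 0, n_tips)]
    while stack:
        node, lo, hi = stack.pop()
        size = hi - lo
        if size == 1:
            node.taxon = taxon_ns.new_taxon(labels[order[lo]])
            continue
        split = lo + int(rng.integers(1, size))
        left = node.new_child()
        right = node.new_child()
        # push right first so the left half is expanded first (LIFO)
        stack.append((right, split, hi))
        stack.append((left, lo, split))
    seed_node = tree.seed_node
    for node in tree.preorder_node_iter():
        if node is not seed_node:
            node.edge.length = float(rng.uniform(0.0, 1.0))
    return Phylogeny(tree)


def tree_signature(tree: Phylogeny) -> list[tuple[tuple[str, ...], float | None]]:
    """Canonical representation of a rooted tree: for every node, the sorted
    tuple of tip labels below it plus that node's edge length. Two rooted
    trees are identical in topology, labels and branch lengths iff their
    signatures are equal (used by tests and round-trip checks)."""
    sig = []
    for node in tree.dendropy_tree.postorder_node_iter():
        if node.is_leaf():
            clade = (node.taxon.label,)
        else:
            clade = tuple(sorted(l.taxon.label for l in node.leaf_iter()))
        sig.append((clade, node.edge.length))
    return sorted(sig)


def trees_equal(a: Phylogeny, b: Phylogeny, rel_tol: float = 0.0) -> bool:
    """True if two rooted trees agree in topology and labels, with branch
    lengths equal within ``rel_tol`` relative tolerance."""
    sig_a, sig_b = tree_signature(a), tree_signature(b)
    if len(sig_a) != len(sig_b):
        return False
    for (clade_a, len_a), (clade_b, len_b) in zip(sig_a, sig_b):
        if clade_a != clade_b:
            return False
        if (len_a is None) != (len_b is None):
            return False
        if len_a is not None:
            scale = max(abs(len_a), abs(len_b), 1e-300)
            if abs(len_a - len_b) > rel_tol * scale and len_a != len_b:
                return False
    return True
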