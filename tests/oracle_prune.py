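"""Brute-force pruning oracle for tests.

Independent of the package's pruning path: converts a tree to a plain
node structure, deletes unwanted tips ONE AT A TIME, and after each deletion
suppresses single-child nodes by merging edge lengths (a suppressed chain
above the root leaves its accumulated length on the new root). Produces the
same canonical signature as ``tree_ops.tree_signature`` for comparison.
"""

from __future__ import annotations


class _Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length
        self.children: list[_Node] = []
        self.parent: _Node | None = None

    def add(self, child: "_Node") -> None:
        child.parent = self
        self.children.append(child)


def _from_phylogeny(tree) -> _Node:
    def build(dnode) -> _Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = _Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add(build(child))
        return node

    return build(tree.dendropy_tree.seed_node)


def _merge(a, b):
    if a is None and b is None:
        return None
    return (a or 0.0) + (b or 0.0)


def _suppress_unifurcations(root: _Node) -> _Node:
    changed = True
    while changed:
        changed = False
        # root chain: single-child root is replaced by its child, which
        # inherits the accumulated length as its own (root) edge length
        if len(root.children) == 1:
            child = root.children[0]
            child.length = _merge(child.length, root.length)
            child.parent = None
            root = child
            changed = True
            continue
        stack = [root]
        while stack:
            node = stack.pop()
            for i, child in enumerate(list(node.children)):
                if child.children and len(child.children) == 1:
                    grandchild = child.children[0]
                    grandchild.length = _merge(grandchild.length, child.length)
                    grandchild.parent = node
                    node.children[i] = grandchild
                    changed = True
                else:
                    stack.append(child)
    return root


def _delete_leaf(root: _Node, label: str) -> _Node:
    stack = [root]
    target = None
    while stack:
        node = stack.pop()
        for child in node.children:
            if not child.children and child.label == label:
                target = child
                break
            stack.append(child)
        if target:
            break
    assert target is not None, f"oracle: leaf {label!r} not found"
    target.parent.children.remove(target)
    return _suppress_unifurcations(root)


def oracle_prune_signature(tree, keep: set[str]):
    """Signature (sorted clade/edge-length pairs) of the tree obtained by
    sequentially deleting every tip not in ``keep``."""
    root = _from_phylogeny(tree)
    for label in tree.tip_labels:
        if label not in keep:
            root = _delete_leaf(root, label)

    sig = []

    def walk(node: _Node) -> tuple[str, ...]:
        if not node.children:
            clade = (node.label,)
        else:
            tips: list[str] = []
            for child in node.children:
                tips.extend(walk(child))
            clade = tuple(sorted(tips))
        sig.append((clade, node.length))
        return clade

    walk(root)
    return sorted(sig)
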