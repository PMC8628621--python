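"""Newick reading and writing, and the tree containers built on them.

Labels are treated literally: no underscore-to-space translation is performed
in either direction, so the strings stored on tips are exactly the strings
that appear in the source text (minus surrounding single quotes). This avoids
silent mismatches when tip labels are later matched against a trait table.
"""

from __future__ import annotations

import io
from collections.abc import Iterable, Iterator

import dendropy
from dendropy.utility import error as _dendropy_error

from .errors import NewickParseError, TreeValidationError

__all__ = ["Phylogeny", "TreeSet", "parse_newick", "write_newick"]


class Phylogeny:
    """A rooted phylogenetic tree with uniquely labeled tips.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the package's
    structural invariants on construction: unique non-empty tip labels and
    non-negative branch lengths. Polytomies are permitted; branch lengths and
    internal-node labels are optional. Internal labels are preserved on
    read/write but ignored by all coupling logic.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._validate()

    def _validate(self) -> None:
        labels: list[str] = []
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise TreeValidationError("tree contains an unlabeled tip")
            labels.append(leaf.taxon.label)
        if len(labels) != len(set(labels)):
            dup = sorted({l for l in labels if labels.count(l) > 1})
            raise TreeValidationError(f"duplicate tip labels within one tree: {dup}")
        if not labels:
            raise TreeValidationError("tree has no tips")
        for edge in self._tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeValidationError(f"negative branch length: {edge.length}")

    # -- structure -----------------------------------------------------

    @property
    def tip_labels(self) -> list[str]:
        """Tip labels in left-to-right traversal order."""
        return [leaf.taxon.label for leaf in self._tree.leaf_node_iter()]

    @property
    def tip_set(self) -> frozenset[str]:
        return frozenset(self.tip_labels)

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self._tree.preorder_node_iter())

    @property
    def has_branch_lengths(self) -> bool:
        """True if every non-root edge carries a length."""
        seed = self._tree.seed_node
        return all(
            node.edge.length is not None
            for node in self._tree.preorder_node_iter()
            if node is not seed
        )

    @property
    def root_edge_length(self) -> float | None:
        """Length on the root's own edge, if any (appears after pruning away
        everything outside a subtree; keeps total tree depth)."""
        return self._tree.seed_node.edge.length

    # -- lifecycle -----------------------------------------------------

    def copy(self) -> "Phylogeny":
        """Independent structural copy; mutating it never affects the source."""
        cloned = self._tree.clone(depth=1)
        cloned.migrate_taxon_namespace(dendropy.TaxonNamespace())
        return Phylogeny(cloned)

    def as_newick(self, precision: int = 6) -> str:
        """Single semicolon-terminated Newick statement for this tree."""
        return _tree_to_newick(self._tree, precision)

    @classmethod
    def from_newick(cls, text: str) -> "Phylogeny":
        """Parse exactly one tree from a Newick string."""
        trees = parse_newick(text)
        if len(trees) != 1:
            raise NewickParseError(f"expected exactly one tree, found {len(trees)}")
        return trees[0]

    # -- dunder --------------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        """The underlying dendropy tree (mutate at your own risk)."""
        return self._tree

    def __repr__(self) -> str:
        return f"<Phylogeny: {self.n_tips} tips, {self.n_nodes} nodes>"


class TreeSet:
    """Ordered collection of one or more trees handled together.

    The coupling layer forces every member onto a common tip sample; a raw
    TreeSet straight from a multi-tree file may still hold trees with
    differing tip sets (``has_uniform_tips`` reports which).
    """

    def __init__(self, trees: Iterable[Phylogeny]):
        trees = list(trees)
        if not trees:
            raise TreeValidationError("a TreeSet requires at least one tree")
        for t in trees:
            if not isinstance(t, Phylogeny):
                raise TypeError(f"TreeSet members must be Phylogeny, got {type(t).__name__}")
        self._trees = trees

    @property
    def trees(self) -> list[Phylogeny]:
        return list(self._trees)

    def __len__(self) -> int:
        return len(self._trees)

    def __iter__(self) -> Iterator[Phylogeny]:
        return iter(self._trees)

    def __getitem__(self, i: int) -> Phylogeny:
        return self._trees[i]

    @property
    def has_uniform_tips(self) -> bool:
        first = self._trees[0].tip_set
        return all(t.tip_set == first for t in self._trees[1:])

    def common_tips(self) -> frozenset[str]:
        """Intersection of all member trees' tip sets."""
        common = set(self._trees[0].tip_set)
        for t in self._trees[1:]:
            common &= t.tip_set
        return frozenset(common)

    def copy(self) -> "TreeSet":
        return TreeSet(t.copy() for t in self._trees)

    def __repr__(self) -> str:
        return f"<TreeSet: {len(self)} tree(s), {self._trees[0].n_tips} tips in first>"


def parse_newick(text: str) -> TreeSet:
    """Parse one or more semicolon-terminated Newick statements.

    Trees may be separated by newlines or appear on one line. Bare and
    single-quoted labels are both accepted; quoted labels are stored without
    the quotes. Underscores are never translated to spaces.

    Raises
    ------
    NewickParseError
        On empty input or malformed Newick (with line/column where known).
    TreeValidationError
        On duplicate tip labels within one tree, unlabeled tips, or
        negative branch lengths.
    """
    if not text or not text.strip():
        raise NewickParseError("empty input: no Newick statement found")
    try:
        tree_list = dendropy.TreeList.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except _dendropy_error.DataParseError as exc:
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        msg = getattr(exc, "message", None) or str(exc)
        if "duplicate" in msg.lower():
            raise TreeValidationError(f"duplicate tip labels within one tree: {msg}") from exc
        raise NewickParseError(msg, line=line, column=col) from exc
    if len(tree_list) == 0:
        raise NewickParseError("empty input: no Newick statement found")
    phylos = []
    for tree in tree_list:
        tree.migrate_taxon_namespace(dendropy.TaxonNamespace())
        phylos.append(Phylogeny(tree))
    return TreeSet(phylos)


def write_newick(trees: TreeSet | Phylogeny, precision: int = 6) -> str:
    """Serialize trees to Newick, one semicolon-terminated statement per line.

    ``precision`` is the number of significant digits for branch lengths
    (>= 1). Labels containing Newick metacharacters or spaces are
    single-quoted; underscores in labels stay literal and unquoted.
    """
    if precision < 1:
        raise ValueError(f"precision must be >= 1, got {precision}")
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])
    return "".join(_tree_to_newick(t.dendropy_tree, precision) for t in trees)


def _tree_to_newick(tree: dendropy.Tree, precision: int) -> str:
    out = io.StringIO()
    tree.write(
        file=out,
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        preserve_spaces=True,
        real_value_format_specifier=f".{precision}g",
    )
    return out.getvalue()
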