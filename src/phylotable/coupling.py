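"""Coupled tree/trait-table objects.

A :class:`CoupledTreeData` holds one or more trees plus a character matrix
matched by taxon name, and maintains the coupling invariant through every
subsequent operation: the set of table labels equals the tip set of every
tree, with exactly one row per tip, and rows ordered by the first tree's tip
traversal order. Operations that change the row set prune the trees to the
surviving taxa; aggregations that collapse rows (so no row-to-taxon bijection
remains) detach the result from the trees and return a plain table with a
warning.

Matching is case-sensitive exact string equality on labels: no trimming and
no underscore/space folding, consistent with the literal Newick labels.
"""

from __future__ import annotations

import warnings
from collections.abc import Callable, Iterable, Sequence
from dataclasses import dataclass, field

import pandas as pd

from .characters import detect_all_characters, CharacterType
from .errors import (
    DetachedTableWarning,
    MatchError,
    QueryError,
    TableValidationError,
    TiedColumnsWarning,
)
from .newick import Phylogeny, TreeSet
from .table import TraitTable
from .tree_ops import prune_to

__all__ = [
    "CoupledTreeData",
    "MatchReport",
    "CouplingSummary",
    "match",
    "drop_taxa",
    "query",
    "extract_vector",
    "pull",
    "apply_external",
    "summarize",
    "peek",
]


@dataclass
class MatchReport:
    """Record of the tree/table matching step."""

    label_column: str
    n_matched: int
    n_tips_dropped: int
    n_rows_dropped: int
    n_duplicate_rows_dropped: int
    per_tree_tips_dropped: list[int] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "label_column": self.label_column,
            "n_matched": self.n_matched,
            "n_tips_dropped": self.n_tips_dropped,
            "n_rows_dropped": self.n_rows_dropped,
            "n_duplicate_rows_dropped": self.n_duplicate_rows_dropped,
            "per_tree_tips_dropped": list(self.per_tree_tips_dropped),
        }


@dataclass
class CouplingSummary:
    """Summary of a coupled object: taxa/tree counts, character-type counts,
    missing cells, and cumulative changes since construction."""

    n_taxa: int
    n_trees: int
    n_discrete: int
    n_continuous: int
    n_missing: int
    dropped_tips_total: int
    dropped_rows_total: int

    def __str__(self) -> str:
        return (
            f"Coupled tree/data object\n"
            f"  taxa:        {self.n_taxa}\n"
            f"  trees:       {self.n_trees}\n"
            f"  characters:  {self.n_discrete} discrete, {self.n_continuous} continuous\n"
            f"  missing:     {self.n_missing} cell(s)\n"
            f"  changes:     {self.dropped_tips_total} tip(s), "
            f"{self.dropped_rows_total} row(s) dropped since construction"
        )


class CoupledTreeData:
    """Trees and trait table coupled by taxon name.

    Construct via :func:`match`; all public operations return new objects and
    never mutate their input. ``dropped_tips_total`` / ``dropped_rows_total``
    accumulate every taxon removed after construction (explicit drops and
    coupled row filters alike).
    """

    def __init__(
        self,
        trees: TreeSet,
        table: TraitTable,
        dropped_tips_total: int = 0,
        dropped_rows_total: int = 0,
        _validated: bool = False,
    ):
        if table.label_column is None:
            raise TableValidationError("coupled table must have a label column")
        self.trees = trees
        self.table = table
        self.dropped_tips_total = dropped_tips_total
        self.dropped_rows_total = dropped_rows_total
        if not _validated:
            self._check_invariant()

    def _check_invariant(self) -> None:
        labels = self.table.labels
        label_set = set(labels)
        if len(label_set) != len(labels):
            raise TableValidationError("coupling broken: duplicate rows per taxon")
        for i, tree in enumerate(self.trees):
            if tree.tip_set != label_set:
                raise TableValidationError(
                    f"coupling broken: tree {i + 1} tip set differs from table labels"
                )
        first_order = self.trees[0].tip_labels
        if labels != first_order:
            raise TableValidationError(
                "coupling broken: row order differs from first tree's tip order"
            )

    # convenience -------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        """Taxon labels in the first tree's tip order (== row order)."""
        return self.table.labels

    @property
    def n_taxa(self) -> int:
        return self.table.n_rows

    def __repr__(self) -> str:
        return (
            f"<CoupledTreeData: {self.n_taxa} taxa, {len(self.trees)} tree(s), "
            f"{len(self.table.trait_columns)} characters>"
        )

    # operations (delegate to module functions) -------------------------

    def drop_taxa(self, labels: Iterable[str]) -> "CoupledTreeData":
        return drop_taxa(self, labels)

    def query(self, **kwargs):
        return query(self, **kwargs)

    def extract_vector(self, *traits: str):
        return extract_vector(self, *traits)

    def pull(self, what: str):
        return pull(self, what)

    def apply_external(self, fn: Callable):
        return apply_external(self, fn)

    def summarize(self) -> CouplingSummary:
        return summarize(self)

    def peek(self, which: str = "head", n: int = 6) -> str:
        return peek(self, which, n)


# ---------------------------------------------------------------------------
# construction


def match(
    trees: TreeSet | Phylogeny,
    table: TraitTable | pd.DataFrame,
    label_column: str | None = None,
) -> tuple[CoupledTreeData, MatchReport]:
    """Match trees to a trait table by taxon name and build a coupled object.

    If ``label_column`` is not given, every column is scored by how many of
    its values (compared as strings, case-sensitively) occur among the first
    tree's tip labels; the best-scoring column is chosen, leftmost on ties
    (a :class:`TiedColumnsWarning` lists tied candidates). The matched taxon
    set is the intersection of the chosen column's values with the tip sets
    of *all* trees (every tree in a set shares one tip sample); each tree is
    pruned to it, unmatched rows are removed, duplicate-label rows keep their
    first occurrence, and rows are reordered to the first tree's tip order.

    Returns the coupled object and a :class:`MatchReport` of what was
    dropped.
    """
    if isinstance(trees, Phylogeny):
        trees = TreeSet([trees])
    if not isinstance(table, TraitTable):
        table = TraitTable(table)
    if table.n_columns < 1:
        raise TableValidationError("table must have at least one column")
    df = table.data

    first_tips = trees[0].tip_set
    if label_column is None:
        counts = {
            col: int(df[col].dropna().astype(str).isin(first_tips).sum())
            for col in df.columns
        }
        best = max(counts.values())
        if best == 0:
            raise MatchError("no overlap between tree and data")
        tied = [c for c in df.columns if counts[c] == best]
        label_column = tied[0]
        if len(tied) > 1:
            warnings.warn(
                f"columns tied for most tip-label matches: {tied}; "
                f"using leftmost {label_column!r}",
                TiedColumnsWarning,
                stacklevel=2,
            )
    elif label_column not in df.columns:
        raise TableValidationError(f"label column {label_column!r} not found in table")

    labels = df[label_column].astype(str)
    common_tips = trees.common_tips()
    matched = set(labels) & common_tips
    if len(matched) == 0:
        raise MatchError("no overlap between tree and data")
    if len(matched) < 2:
        raise MatchError(
            f"only {len(matched)} taxon shared between trees and table; need at least 2"
        )

    per_tree_dropped = [len(t.tip_set - matched) for t in trees]
    pruned = TreeSet(
        prune_to(t, matched) if t.tip_set != matched else t.copy() for t in trees
    )

    in_matched = labels.isin(matched)
    dup_mask = labels.duplicated(keep="first") & in_matched
    keep_mask = in_matched & ~dup_mask
    n_dups = int(dup_mask.sum())
    n_rows_dropped = int((~in_matched).sum())

    kept = df.loc[keep_mask].copy()
    kept[label_column] = labels.loc[keep_mask]
    kept = _reorder_to_tree(kept, label_column, pruned[0])

    report = MatchReport(
        label_column=str(label_column),
        n_matched=len(matched),
        n_tips_dropped=sum(per_tree_dropped),
        n_rows_dropped=n_rows_dropped,
        n_duplicate_rows_dropped=n_dups,
        per_tree_tips_dropped=per_tree_dropped,
    )
    ctd = CoupledTreeData(pruned, TraitTable(kept, label_column=str(label_column)))
    return ctd, report


def _reorder_to_tree(df: pd.DataFrame, label_column: str, tree: Phylogeny) -> pd.DataFrame:
    order = {lab: i for i, lab in enumerate(tree.tip_labels)}
    return (
        df.assign(_tip_order=df[label_column].map(order))
        .sort_values("_tip_order", kind="stable")
        .drop(columns="_tip_order")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# coupled operations


def drop_taxa(ctd: CoupledTreeData, labels: Iterable[str]) -> CoupledTreeData:
    """Remove the given taxa from the table and from every tree."""
    labels = set(labels)
    if not labels:
        return CoupledTreeData(
            ctd.trees.copy(),
            ctd.table.copy(),
            ctd.dropped_tips_total,
            ctd.dropped_rows_total,
            _validated=True,
        )
    current = set(ctd.taxa)
    unknown = labels - current
    if unknown:
        raise TableValidationError(f"unknown taxon label(s): {sorted(unknown)}")
    remaining = current - labels
    if len(remaining) < 2:
        raise MatchError(
            f"cannot drop {len(labels)} taxa: fewer than 2 would remain"
        )
    return _rebuild(ctd, remaining)


def _rebuild(ctd: CoupledTreeData, surviving: set[str], new_df: pd.DataFrame | None = None) -> CoupledTreeData:
    """Prune trees and rows to ``surviving`` taxa, keeping counters."""
    n_removed = ctd.n_taxa - len(surviving)
    trees = TreeSet(
        prune_to(t, surviving) if t.tip_set != surviving else t.copy()
        for t in ctd.trees
    )
    label = ctd.table.label_column
    df = ctd.table.data if new_df is None else new_df
    kept = df[df[label].isin(surviving)]
    kept = _reorder_to_tree(kept, label, trees[0])
    return CoupledTreeData(
        trees,
        TraitTable(kept, label_column=label),
        ctd.dropped_tips_total + n_removed,
        ctd.dropped_rows_total + n_removed,
    )


def query(
    ctd: CoupledTreeData,
    where: str | Callable[[pd.DataFrame], pd.Series] | None = None,
    select: dict | Sequence[str] | None = None,
    group_by: str | Sequence[str] | None = None,
    head: int | None = None,
    tail: int | None = None,
    aggregate: dict | None = None,
) -> CoupledTreeData | TraitTable:
    """Relational query with three-stage row/column/group semantics.

    Stages mirror the ``DT[i, j, by]`` contract of high-performance table
    engines: ``where`` selects rows; ``select``/``head``/``tail``/
    ``aggregate`` transform columns or collapse rows; ``group_by`` partitions
    rows first.

    Parameters
    ----------
    where : str or callable, optional
        Row predicate. A string is evaluated by the pandas query engine
        (comparisons ``== != < <= > >=`` on columns vs literals, combined
        with ``&``/``|`` and parentheses; strings quoted); a callable
        receives the DataFrame and returns a boolean mask.
    select : dict or sequence of str, optional
        Per-row column selection/derivation. A sequence names existing
        columns to keep; a dict maps new column names to expressions
        (evaluated by pandas ``eval``) or callables of the DataFrame
        returning one value per row. Row count is unchanged.
    group_by : str or sequence of str, optional
        Grouping columns; requires ``head``, ``tail`` or ``aggregate``.
    head, tail : int, optional
        Keep the first/last ``n`` source rows (per group when ``group_by``
        is given).
    aggregate : dict, optional
        Row-collapsing summaries: maps output names to ``(column, func)``
        pairs (func a name like "sum"/"mean" or a callable) or to callables
        of the whole (sub-)DataFrame.

    Returns
    -------
    CoupledTreeData or TraitTable
        While every output row still derives from exactly one source row
        (pure filter, per-row derivation, per-group head/tail) the result
        stays coupled: the taxon-label column is implicitly retained and the
        trees are pruned to the surviving taxa. An ``aggregate`` collapses
        rows, so the result detaches from the trees and is returned as a
        plain :class:`TraitTable` with a :class:`DetachedTableWarning`.
    """
    label = ctd.table.label_column
    df = ctd.table.data

    if head is not None and tail is not None:
        raise QueryError("specify at most one of head/tail")
    if group_by is not None and aggregate is None and head is None and tail is None:
        raise QueryError(
            "group_by requires an aggregation or a per-group head/tail; "
            "a grouped per-row derivation has no row-to-taxon meaning here"
        )
    if isinstance(group_by, str):
        group_by = [group_by]
    if group_by:
        missing = [c for c in group_by if c not in df.columns]
        if missing:
            raise QueryError(f"unknown group_by column(s): {missing}")

    # stage (i): row filter
    if where is not None:
        df = _apply_where(df, where)

    # stage (ii)/(iii): aggregation detaches from the trees
    if aggregate is not None:
        result = _apply_aggregate(df, aggregate, group_by)
        warnings.warn(
            "aggregation collapsed rows: result is detached from the trees",
            DetachedTableWarning,
            stacklevel=2,
        )
        return TraitTable(result)

    # per-group (or global) head/tail keeps a row<->taxon bijection
    if head is not None or tail is not None:
        n = head if head is not None else tail
        if n < 1:
            raise QueryError("head/tail count must be >= 1")
        if group_by:
            grouped = df.groupby(group_by, sort=False, dropna=False)
            df = grouped.head(n) if head is not None else grouped.tail(n)
        else:
            df = df.head(n) if head is not None else df.tail(n)

    # per-row column selection/derivation; taxon labels implicitly retained
    if select is not None:
        df = _apply_select(df, select, label)

    surviving = set(df[label])
    if len(surviving) < 2:
        raise QueryError(f"query leaves {len(surviving)} taxa; need at least 2")
    return _rebuild(ctd, surviving, new_df=df)


def _apply_where(df: pd.DataFrame, where) -> pd.DataFrame:
    if callable(where):
        mask = where(df)
        try:
            return df[pd.Series(mask, index=df.index).astype(bool)]
        except (ValueError, TypeError) as exc:
            raise QueryError(f"row predicate did not yield a boolean mask: {exc}") from exc
    try:
        return df.query(where)
    except Exception as exc:  # pandas raises a zoo of engine errors
        raise QueryError(f"invalid row filter {where!r}: {exc}") from exc


def _apply_select(df: pd.DataFrame, select, label: str) -> pd.DataFrame:
    if isinstance(select, dict):
        out = pd.DataFrame(index=df.index)
        out[label] = df[label]
        for name, expr in select.items():
            try:
                values = expr(df) if callable(expr) else df.eval(expr)
            except Exception as exc:
                raise QueryError(f"invalid column expression for {name!r}: {exc}") from exc
            values = pd.Series(values, index=df.index)
            if len(values) != len(df):
                raise QueryError(
                    f"column expression {name!r} changed the row count; "
                    "use aggregate= for row-collapsing summaries"
                )
            out[name] = values
        return out
    cols = list(select)
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise QueryError(f"unknown column(s) in select: {missing}")
    if label not in cols:
        cols = [label] + cols
    return df[cols]


def _apply_aggregate(df: pd.DataFrame, aggregate: dict, group_by) -> pd.DataFrame:
    def agg_one(sub: pd.DataFrame) -> pd.Series:
        row = {}
        for name, spec in aggregate.items():
            try:
                if callable(spec):
                    row[name] = spec(sub)
                else:
                    col, func = spec
                    if col not in sub.columns:
                        raise QueryError(f"unknown column {col!r} in aggregate")
                    row[name] = sub[col].agg(func)
            except QueryError:
                raise
            except Exception as exc:
                raise QueryError(f"aggregation {name!r} failed: {exc}") from exc
        return pd.Series(row)

    if group_by:
        parts = []
        for key, sub in df.groupby(group_by, sort=False, dropna=False):
            key = key if isinstance(key, tuple) else (key,)
            parts.append(pd.concat([pd.Series(dict(zip(group_by, key))), agg_one(sub)]))
        return pd.DataFrame(parts).reset_index(drop=True)
    return agg_one(df).to_frame().T


# ---------------------------------------------------------------------------
# extraction


def extract_vector(ctd: CoupledTreeData, *traits: str):
    """Extract one named vector (a pandas Series keyed by taxon label, in the
    first tree's tip order) per requested trait. A single trait returns the
    Series itself; several return a list of Series."""
    if not traits:
        raise TableValidationError("no trait names given")
    out = []
    for trait in traits:
        if trait not in ctd.table.data.columns or trait == ctd.table.label_column:
            raise TableValidationError(f"unknown trait: {trait!r}")
        series = pd.Series(
            ctd.table.data[trait].to_numpy(),
            index=pd.Index(ctd.taxa, name=ctd.table.label_column),
            name=trait,
        )
        out.append(series)
    return out[0] if len(out) == 1 else out


def pull(ctd: CoupledTreeData, what: str) -> TraitTable | TreeSet:
    """Return an independent copy of the table ("table") or trees ("trees")."""
    if what == "table":
        return ctd.table.copy()
    if what == "trees":
        return ctd.trees.copy()
    raise ValueError(f"what must be 'table' or 'trees', got {what!r}")


def apply_external(ctd: CoupledTreeData, fn: Callable):
    """Apply a caller-supplied ``fn(tree, table)`` to the coupled data.

    With a single tree the single result is returned; with several trees
    ``fn`` runs once per tree against the shared table and a list of results
    is returned in tree order. Exceptions raised by ``fn`` propagate
    unmodified, annotated with the (1-based) tree index.
    """
    results = []
    for i, tree in enumerate(ctd.trees):
        try:
            results.append(fn(tree, ctd.table))
        except Exception as exc:
            exc.add_note(f"raised while applying external function to tree {i + 1}")
            raise
    return results[0] if len(ctd.trees) == 1 else results


def summarize(ctd: CoupledTreeData) -> CouplingSummary:
    """Count taxa, trees, discrete/continuous characters, missing cells and
    cumulative drops."""
    types = detect_all_characters(ctd.table)
    trait_df = ctd.table.data[ctd.table.trait_columns]
    return CouplingSummary(
        n_taxa=ctd.n_taxa,
        n_trees=len(ctd.trees),
        n_discrete=sum(1 for t in types.values() if t is CharacterType.DISCRETE),
        n_continuous=sum(1 for t in types.values() if t is CharacterType.CONTINUOUS),
        n_missing=int(trait_df.isna().sum().sum()),
        dropped_tips_total=ctd.dropped_tips_total,
        dropped_rows_total=ctd.dropped_rows_total,
    )


def peek(ctd: CoupledTreeData, which: str = "head", n: int = 6) -> str:
    """Render the first/last ``n`` table rows plus one summary line per tree.
    Never mutates the object."""
    if which not in {"head", "tail"}:
        raise ValueError(f"which must be 'head' or 'tail', got {which!r}")
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    df = ctd.table.data
    shown = df.head(n) if which == "head" else df.tail(n)
    lines = [shown.to_string()]
    for i, tree in enumerate(ctd.trees):
        lines.append(f"tree {i + 1}: {tree.n_tips} tips, {tree.n_nodes} nodes")
    return "\n".join(lines)
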