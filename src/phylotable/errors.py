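"""Exception and warning types shared across the package."""


class PhylotableError(Exception):
    """Base class for all errors raised by phylotable."""


class NewickParseError(PhylotableError):
    """Malformed Newick input (unbalanced parentheses, empty input, ...).

    Carries the 1-based ``line`` and ``column`` of the offending character
    when the underlying reader reports them.
    """

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        if line is not None or column is not None:
            message = f"{message} (line {line}, column {column})"
        super().__init__(message)
        self.line = line
        self.column = column


class TreeValidationError(PhylotableError):
    """A tree violates a structural invariant (duplicate/empty tip labels,
    negative branch lengths, ...)."""


class PruneError(PhylotableError):
    """Invalid pruning request (unknown labels, fewer than 2 tips kept)."""


class TableValidationError(PhylotableError):
    """A trait table violates an invariant (duplicate column names,
    non-unique taxon labels, unknown columns, ...)."""


class MatchError(PhylotableError):
    """Tree/table matching failed (no overlap, fewer than 2 shared taxa)."""


class QueryError(PhylotableError):
    """A relational query on a coupled object is invalid (bad predicate,
    unknown column, result with fewer than 2 taxa)."""


class TiedColumnsWarning(UserWarning):
    """Several table columns tied for the most tip-label matches; the
    leftmost one was selected."""


class DetachedTableWarning(UserWarning):
    """An aggregation collapsed rows so no row-to-taxon bijection remains;
    the result is a plain table without trees."""
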