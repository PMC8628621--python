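"""Discrete/continuous character detection and name utilities.

A column is classified as discrete if it is non-numeric, or if it is numeric
but takes few distinct values relative to its length: with ``n_distinct``
distinct non-missing values among ``n`` non-missing ones, a numeric column is
discrete when ``n_distinct / n < cutoff`` (default cutoff 0.1) and continuous
otherwise. Numeric-looking strings ("1.5") count as non-numeric unless the
whole column already parses as numeric — strict typing avoids silent
coercion.
"""

from __future__ import annotations

import enum

import pandas as pd

from .errors import TableValidationError
from .table import TraitTable

__all__ = [
    "CharacterType",
    "detect_character_type",
    "detect_all_characters",
    "filter_matrix",
    "has_names",
    "force_names",
]


class CharacterType(enum.Enum):
    DISCRETE = "discrete"
    CONTINUOUS = "continuous"

    @classmethod
    def coerce(cls, value: "CharacterType | str") -> "CharacterType":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).lower())
        except ValueError:
            raise ValueError(
                f"character type must be 'discrete' or 'continuous', got {value!r}"
            ) from None


def detect_character_type(values, cutoff: float = 0.1) -> CharacterType:
    """Classify one character column as discrete or continuous.

    Parameters
    ----------
    values : sequence or pandas.Series
        The column values; missing entries are ignored.
    cutoff : float in (0, 1]
        Distinct-value-ratio threshold below which a numeric column is
        treated as discrete.
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    series = values if isinstance(values, pd.Series) else pd.Series(values)
    non_missing = series.dropna()
    if non_missing.empty:
        raise TableValidationError("cannot detect character type: all values missing")
    if not pd.api.types.is_numeric_dtype(non_missing) or pd.api.types.is_bool_dtype(
        non_missing
    ):
        return CharacterType.DISCRETE
    ratio = non_missing.nunique() / len(non_missing)
    return CharacterType.DISCRETE if ratio < cutoff else CharacterType.CONTINUOUS


def detect_all_characters(
    table: TraitTable, cutoff: float = 0.1
) -> dict[str, CharacterType]:
    """Classify every non-label column of ``table``; errors name the column."""
    out: dict[str, CharacterType] = {}
    for name in table.trait_columns:
        try:
            out[name] = detect_character_type(table.data[name], cutoff=cutoff)
        except TableValidationError as exc:
            raise TableValidationError(f"column {name!r}: {exc}") from exc
    return out


def filter_matrix(
    table: TraitTable, keep: CharacterType | str, cutoff: float = 0.1
) -> TraitTable:
    """Keep only columns of the requested type (plus the label column),
    preserving original column order. May return a label-only table."""
    keep = CharacterType.coerce(keep)
    types = detect_all_characters(table, cutoff=cutoff)
    cols = [
        c
        for c in table.column_names
        if c == table.label_column or types.get(c) == keep
    ]
    return TraitTable(table.data[cols], label_column=table.label_column)


def has_names(table: TraitTable, which: str = "both") -> bool:
    """Check naming: "columns" is true iff every column has a non-empty
    unique string name; "rows" is true iff a label column is designated;
    "both" is their conjunction."""
    if which not in {"rows", "columns", "both"}:
        raise ValueError(f"which must be 'rows', 'columns' or 'both', got {which!r}")
    cols_ok = _column_names_valid(table)
    rows_ok = table.label_column is not None
    if which == "columns":
        return cols_ok
    if which == "rows":
        return rows_ok
    return cols_ok and rows_ok


def force_names(table: TraitTable, which: str = "both") -> TraitTable:
    """Return a table with valid names for rows, columns or both.

    Invalid or duplicate column names are replaced by "V1".."Vk" by position.
    A missing label designation is resolved by designating the first column
    whose values are unique non-missing strings; if none qualifies, a
    synthetic label column "taxon" with values "taxon_1".."taxon_n" is
    prepended. Idempotent.
    """
    if which not in {"rows", "columns", "both"}:
        raise ValueError(f"which must be 'rows', 'columns' or 'both', got {which!r}")
    df = table.data.copy()
    label = table.label_column

    if which in {"columns", "both"} and not _column_names_valid(table):
        seen: set[str] = set()
        new_names = []
        for i, name in enumerate(df.columns):
            ok = isinstance(name, str) and name.strip() and name not in seen
            new = name if ok else f"V{i + 1}"
            if label is not None and name == label and not ok:
                label = new
            seen.add(new)
            new_names.append(new)
        df.columns = new_names

    if which in {"rows", "both"} and label is None:
        for name in df.columns:
            col = df[name]
            if col.isna().any():
                continue
            as_str = col.astype(str)
            if not pd.api.types.is_numeric_dtype(col) and as_str.is_unique:
                label = name
                break
        if label is None:
            label = "taxon"
            df.insert(0, label, [f"taxon_{i + 1}" for i in range(len(df))])

    return TraitTable(df, label_column=label)


def _column_names_valid(table: TraitTable) -> bool:
    names = table.column_names
    return (
        all(isinstance(n, str) and n.strip() for n in names)
        and len(set(names)) == len(names)
    )
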