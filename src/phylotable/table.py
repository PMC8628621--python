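"""The trait table: a rectangular character matrix with a taxon-label column.

Backed by a pandas DataFrame. One row per taxon, one column per character;
one column may be designated as the taxon-label column, in which case its
values must be unique, non-missing strings (they are the keys used to couple
the table to tree tips).
"""

from __future__ import annotations

import os

import pandas as pd

from .errors import TableValidationError

__all__ = ["TraitTable"]


class TraitTable:
    """Character matrix wrapper enforcing table invariants.

    Parameters
    ----------
    data : pandas.DataFrame
        The character matrix (copied on construction).
    label_column : str, optional
        Name of the column holding taxon labels. When set, its values are
        coerced to ``str`` and must be unique and non-missing.
    """

    def __init__(self, data: pd.DataFrame, label_column: str | None = None):
        if not isinstance(data, pd.DataFrame):
            data = pd.DataFrame(data)
        self._df = data.copy()
        self._df.reset_index(drop=True, inplace=True)
        names = list(self._df.columns)
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise TableValidationError(f"duplicate column names: {dup}")
        self._label_column = None
        if label_column is not None:
            self._set_label_column(label_column)

    def _set_label_column(self, name: str) -> None:
        if name not in self._df.columns:
            raise TableValidationError(f"label column {name!r} not found in table")
        col = self._df[name]
        if col.isna().any():
            raise TableValidationError(f"label column {name!r} has missing values")
        labels = col.astype(str)
        if labels.duplicated().any():
            dup = sorted(labels[labels.duplicated()].unique())
            raise TableValidationError(f"label column {name!r} has duplicate labels: {dup}")
        self._df[name] = labels
        self._label_column = name

    # -- accessors -------------------------------------------------------

    @property
    def data(self) -> pd.DataFrame:
        """The underlying DataFrame (a live view; use ``copy()`` to detach)."""
        return self._df

    @property
    def label_column(self) -> str | None:
        return self._label_column

    @property
    def labels(self) -> list[str]:
        """Taxon labels in row order; requires a designated label column."""
        if self._label_column is None:
            raise TableValidationError("no label column designated")
        return self._df[self._label_column].tolist()

    @property
    def column_names(self) -> list[str]:
        return list(self._df.columns)

    @property
    def trait_columns(self) -> list[str]:
        """All column names except the label column."""
        return [c for c in self._df.columns if c != self._label_column]

    @property
    def n_rows(self) -> int:
        return len(self._df)

    @property
    def n_columns(self) -> int:
        return self._df.shape[1]

    def copy(self) -> "TraitTable":
        return TraitTable(self._df, label_column=self._label_column)

    def __len__(self) -> int:
        return len(self._df)

    def __repr__(self) -> str:
        lab = f", labels={self._label_column!r}" if self._label_column else ""
        return f"<TraitTable: {self.n_rows} rows x {self.n_columns} columns{lab}>"

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def read_csv(
        cls,
        path: str | os.PathLike,
        label_column: str | None = None,
        delimiter: str | None = None,
    ) -> "TraitTable":
        """Read a delimited character matrix with a header row.

        The delimiter is inferred from the extension (``.tsv``/``.txt`` ->
        tab, otherwise comma) unless given. Empty cells and "NA" are read as
        missing.
        """
        if delimiter is None:
            ext = os.path.splitext(os.fspath(path))[1].lower()
            delimiter = "\t" if ext in {".tsv", ".txt", ".tab"} else ","
        df = pd.read_csv(path, sep=delimiter)
        return cls(df, label_column=label_column)

    def write_csv(self, path: str | os.PathLike, delimiter: str | None = None) -> None:
        if delimiter is None:
            ext = os.path.splitext(os.fspath(path))[1].lower()
            delimiter = "\t" if ext in {".tsv", ".txt", ".tab"} else ","
        self._df.to_csv(path, sep=delimiter, index=False)
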