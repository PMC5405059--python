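"""Contingency-table data model, validation, canonicalization, and CSV/TSV I/O.

The table convention throughout the package: rows index the first categorical
variable (the groups, when one margin is fixed by design), columns the second.
A dot in the classical notation indicates summation over an index, so for a
table ``y`` the row totals are ``y_r.``, the column totals ``y_.c``, and the
grand total ``y..``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "TableValidationError",
    "TableShapeError",
    "TableParseError",
    "ContingencyTable",
    "CanonicalTransform",
    "make_table",
    "margins",
    "canonicalize_min_margin",
    "read_table",
    "write_table",
    "load_example",
    "EXAMPLE_TABLES",
]


class TableValidationError(ValueError):
    """A count matrix violates the contingency-table invariants."""


class TableShapeError(TableValidationError):
    """A table does not have the required dimensions."""


class TableParseError(ValueError):
    """A CSV/TSV file could not be parsed as an integer count matrix."""


@dataclass(frozen=True)
class ContingencyTable:
    """A validated R x C matrix of non-negative integer counts.

    Instances should be built through :func:`make_table` or
    :func:`read_table`, which enforce the invariants (integer entries >= 0,
    at least two rows and two columns, grand total >= 1).
    """

    counts: np.ndarray
    row_labels: tuple[str, ...] | None = None
    col_labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=np.int64))
        self.counts.setflags(write=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def n_rows(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cols(self) -> int:
        return self.counts.shape[1]

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> int:
        return int(self.counts.sum())

    def transposed(self) -> "ContingencyTable":
        return ContingencyTable(self.counts.T.copy(), self.col_labels, self.row_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ContingencyTable):
            return NotImplemented
        return (
            np.array_equal(self.counts, other.counts)
            and self.row_labels == other.row_labels
            and self.col_labels == other.col_labels
        )


@dataclass(frozen=True)
class CanonicalTransform:
    """Relabeling applied by :func:`canonicalize_min_margin`."""

    transposed: bool = False
    row_swapped: bool = False
    col_swapped: bool = False

    @property
    def is_identity(self) -> bool:
        return not (self.transposed or self.row_swapped or self.col_swapped)


def make_table(counts, row_labels=None, col_labels=None) -> ContingencyTable:
    """Validate a rectangular matrix of counts and wrap it in a table.

    Raises
    ------
    TableShapeError
        If the matrix has fewer than 2 rows or 2 columns, or is ragged.
    TableValidationError
        If any entry is negative or non-integer (naming the offending cell),
        or if every entry is zero.
    """
    try:
        arr = np.asarray(counts)
    except ValueError as exc:  # ragged nested lists
        raise TableShapeError(f"counts are not a rectangular matrix: {exc}") from exc
    if arr.dtype == object or arr.ndim != 2:
        raise TableShapeError(
            f"counts must be a rectangular 2-D matrix, got shape {arr.shape}"
        )
    if arr.shape[0] < 2 or arr.shape[1] < 2:
        raise TableShapeError(
            f"a contingency table needs at least 2 rows and 2 columns, "
            f"got {arr.shape[0]}x{arr.shape[1]}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(np.asarray(arr, dtype=float))
        bad = np.argwhere(~np.isclose(np.asarray(arr, dtype=float), rounded))
        if bad.size:
            r, c = bad[0]
            raise TableValidationError(
                f"cell ({r + 1},{c + 1}) has non-integer count {arr[r, c]!r}"
            )
        arr = rounded.astype(np.int64)
    neg = np.argwhere(arr < 0)
    if neg.size:
        r, c = neg[0]
        raise TableValidationError(
            f"cell ({r + 1},{c + 1}) has negative count {arr[r, c]}"
        )
    if arr.sum() < 1:
        raise TableValidationError("table is empty: all cell counts are zero")
    if row_labels is not None:
        row_labels = tuple(str(x) for x in row_labels)
        if len(row_labels) != arr.shape[0]:
            raise TableValidationError("row_labels length does not match row count")
    if col_labels is not None:
        col_labels = tuple(str(x) for x in col_labels)
        if len(col_labels) != arr.shape[1]:
            raise TableValidationError("col_labels length does not match column count")
    return ContingencyTable(arr.astype(np.int64), row_labels, col_labels)


def margins(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray, int]:
    """Row totals, column totals, and the grand total of a table."""
    return table.row_totals, table.col_totals, table.grand_total


def canonicalize_min_margin(
    table: ContingencyTable,
) -> tuple[ContingencyTable, CanonicalTransform]:
    """Relabel a 2x2 table so its first row total is the smallest margin.

    The hypergeometric closed form is stated for a table whose first row total
    equals the minimum of the four marginal totals; any 2x2 table can be
    brought into that form by transposing and/or swapping rows.  Ties are
    broken by preferring the identity, then a row swap, then transposition
    (and transposition plus row swap last); any tied choice yields the same
    closed-form value.
    """
    if table.shape != (2, 2):
        raise TableShapeError(f"canonicalization requires a 2x2 table, got {table.shape}")
    r = table.row_totals
    c = table.col_totals
    smallest = min(int(r.min()), int(c.min()))
    if int(r[0]) == smallest:
        return table, CanonicalTransform()
    if int(r[1]) == smallest:
        t = ContingencyTable(table.counts[::-1].copy(), _rev(table.row_labels), table.col_labels)
        return t, CanonicalTransform(row_swapped=True)
    if int(c[0]) == smallest:
        return table.transposed(), CanonicalTransform(transposed=True)
    t = table.transposed()
    t = ContingencyTable(t.counts[::-1].copy(), _rev(t.row_labels), t.col_labels)
    return t, CanonicalTransform(transposed=True, row_swapped=True)


def _rev(labels):
    return labels[::-1] if labels is not None else None


def _sniff_delimiter(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("csv", "tsv"):
            raise ValueError(f"format must be 'csv' or 'tsv', got {fmt!r}")
        return "," if fmt == "csv" else "\t"
    return "\t" if path.suffix.lower() in (".tsv", ".tab") else ","


def read_table(path, fmt: str | None = None, header: bool = False) -> ContingencyTable:
    """Read an integer count matrix from a CSV or TSV file.

    Lines starting with ``#`` are treated as comments.  With ``header=True``
    the first non-comment row holds column labels and the first field of each
    subsequent row holds a row label.

    Raises :class:`TableParseError` (with the offending line number) for
    ragged rows, non-integer cells, or an empty file.
    """
    path = Path(path)
    delim = _sniff_delimiter(path, fmt)
    rows: list[list[str]] = []
    line_nos: list[int] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for lineno, record in enumerate(csv.reader(fh, delimiter=delim), start=1):
            if not record or (record[0].lstrip().startswith("#")):
                continue
            if all(not f.strip() for f in record):
                continue
            rows.append([f.strip() for f in record])
            line_nos.append(lineno)
    if not rows:
        raise TableParseError(f"{path}: file contains no data rows")

    row_labels = col_labels = None
    if header:
        col_labels = [f for f in rows[0] if f != ""]
        body, body_lines = rows[1:], line_nos[1:]
        if not body:
            raise TableParseError(f"{path}: header present but no data rows")
        row_labels = [r[0] for r in body]
        body = [r[1:] for r in body]
        # a header row may or may not include a leading corner cell
        if len(col_labels) == len(body[0]) + 1:
            col_labels = col_labels[1:]
    else:
        body, body_lines = rows, line_nos

    width = len(body[0])
    parsed: list[list[int]] = []
    for record, lineno in zip(body, body_lines):
        if len(record) != width:
            raise TableParseError(
                f"{path}:{lineno}: ragged row has {len(record)} fields, expected {width}"
            )
        out = []
        for j, cell in enumerate(record):
            try:
                out.append(int(cell))
            except ValueError as exc:
                raise TableParseError(
                    f"{path}:{lineno}: field {j + 1} is not an integer: {cell!r}"
                ) from exc
        parsed.append(out)
    try:
        return make_table(parsed, row_labels=row_labels, col_labels=col_labels)
    except TableValidationError as exc:
        raise TableParseError(f"{path}: {exc}") from exc


def write_table(table: ContingencyTable, path, fmt: str | None = None) -> None:
    """Write a table to CSV/TSV, including labels when present."""
    path = Path(path)
    delim = _sniff_delimiter(path, fmt)
    header = table.col_labels is not None
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        if header:
            lead = [""] if table.row_labels is not None else []
            writer.writerow(lead + list(table.col_labels))
        for i, row in enumerate(table.counts):
            lead = [table.row_labels[i]] if table.row_labels is not None else []
            writer.writerow(lead + [int(v) for v in row])


#: Bundled example tables (file stem -> short description).
EXAMPLE_TABLES = {
    "bridges": "2x2 suspension/solid bridge phone-call counts",
    "dolls": "2x2 racial doll-preference counts (160 children)",
    "siblings": "2x2 sibling-acceptance median-split counts (30 children)",
    "occupations": "14x14 fathers/sons occupation counts (775 pairs)",
}


def load_example(name: str) -> ContingencyTable:
    """Load one of the bundled example tables by name.

    Available names: ``bridges``, ``dolls``, ``siblings``, ``occupations``.
    """
    if name not in EXAMPLE_TABLES:
        raise KeyError(f"unknown example {name!r}; choose from {sorted(EXAMPLE_TABLES)}")
    ref = resources.files("ctbf.data").joinpath(f"{name}.csv")
    with resources.as_file(ref) as path:
        return read_table(path, fmt="csv", header=True)
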