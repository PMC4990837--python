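"""Reading and writing proteomics result tables.

Three source formats are supported — XLSX workbooks (one sheet), delimited
text (CSV/TSV, with an optional leading comment block), and mzTab 1.x/2.0
(one section of PRT/PEP/PSM/SML) — and two output formats (XLSX, TSV).
All of them round-trip through :class:`DataTable`, the package's only
in-memory table container: an ordered list of column names plus an ordered
list of rows whose cells are numbers, text, or missing (``None``).

Cells are typed per cell, not per column, because MS result exports freely
mix identifiers, scores, and blanks within one column.
"""

from __future__ import annotations

import csv
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import openpyxl

from .errors import FormatError, InputError, OutputError, SchemaError, SelectorError

Cell = Union[int, float, str, None]

_WS_RUN = re.compile(r"\s+")

#: mzTab data-line token -> its header-line token
MZTAB_SECTIONS = {"PRT": "PRH", "PEP": "PEH", "PSM": "PSH", "SML": "SMH"}


def normalize_name(name: str) -> str:
    """Trim outer whitespace and collapse internal runs to one space.

    Column names are compared case-sensitively after this normalization,
    which absorbs export artifacts like trailing spaces or double spaces
    without guessing at case conventions.
    """
    return _WS_RUN.sub(" ", name.strip())


def parse_cell(text: str) -> Cell:
    """Classify one textual cell: number if it fully parses, empty -> missing.

    Integers stay integral; scientific notation and signed decimals become
    floats. Anything else is kept verbatim as text.
    """
    stripped = text.strip()
    if stripped == "":
        return None
    try:
        return int(stripped)
    except ValueError:
        pass
    try:
        value = float(stripped)
    except ValueError:
        return text
    # reject nan/inf spellings: they are text in a result table
    if math.isnan(value) or math.isinf(value):
        return text
    return value


@dataclass
class DataTable:
    """Ordered rows with named columns; the unit being filtered.

    Invariants (enforced at construction):

    * every row has exactly one cell per column;
    * column names are unique after :func:`normalize_name`;
    * source row order is preserved.
    """

    columns: list[str]
    rows: list[list[Cell]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.columns = [normalize_name(c) for c in self.columns]
        seen: set[str] = set()
        for name in self.columns:
            if name in seen:
                raise SchemaError(f"duplicate column name after normalization: {name!r}")
            seen.add(name)
        for i, row in enumerate(self.rows):
            if len(row) != len(self.columns):
                raise SchemaError(
                    f"row {i} has {len(row)} cells for {len(self.columns)} columns"
                )

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column_index(self, name: str) -> int:
        try:
            return self.columns.index(normalize_name(name))
        except ValueError:
            raise KeyError(name) from None

    def column_values(self, name: str) -> list[Cell]:
        idx = self.column_index(name)
        return [row[idx] for row in self.rows]

    def subset(self, row_indices: Iterable[int]) -> "DataTable":
        """New table with the same columns and the given rows, in given order."""
        return DataTable(list(self.columns), [list(self.rows[i]) for i in row_indices])

    def to_dataframe(self):
        """Bridge to pandas for downstream analysis (missing -> NaN)."""
        import pandas as pd

        return pd.DataFrame(self.rows, columns=self.columns)

    @classmethod
    def from_dataframe(cls, frame) -> "DataTable":
        import pandas as pd

        rows = [
            [None if (isinstance(v, float) and math.isnan(v)) or pd.isna(v) else v for v in rec]
            for rec in frame.itertuples(index=False, name=None)
        ]
        return cls([str(c) for c in frame.columns], rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataTable):
            return NotImplemented
        if self.columns != other.columns or len(self.rows) != len(other.rows):
            return False
        for a, b in zip(self.rows, other.rows):
            for x, y in zip(a, b):
                if not _cells_equal(x, y):
                    return False
        return True


def _cells_equal(x: Cell, y: Cell, rel_tol: float = 1e-9) -> bool:
    if x is None or y is None:
        return x is y
    if isinstance(x, str) or isinstance(y, str):
        return x == y
    if isinstance(x, int) and isinstance(y, int):
        return x == y
    return math.isclose(float(x), float(y), rel_tol=rel_tol, abs_tol=0.0)


def _coerce_xlsx_value(value) -> Cell:
    if value is None:
        return None
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, (int, float)):
        return value
    return parse_cell(str(value))


def read_xlsx(path: str | Path, sheet: str) -> DataTable:
    """Read one worksheet; the first non-empty row is the header."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    try:
        book = openpyxl.load_workbook(path, read_only=True, data_only=True)
    except Exception as exc:  # zip/XML level failures
        raise InputError(f"cannot read XLSX file {path}: {exc}") from exc
    try:
        if sheet not in book.sheetnames:
            raise SelectorError(
                f"sheet {sheet!r} not found in {path}; available sheets: "
                + ", ".join(book.sheetnames)
            )
        ws = book[sheet]
        header: list[str] | None = None
        rows: list[list[Cell]] = []
        for raw in ws.iter_rows(values_only=True):
            if header is None:
                if all(v is None or str(v).strip() == "" for v in raw):
                    continue  # leading blank rows
                header = [str(v) if v is not None else "" for v in raw]
                continue
            cells = [_coerce_xlsx_value(v) for v in raw]
            # pad/truncate against the header width (openpyxl may ragged-pad)
            if len(cells) < len(header):
                cells += [None] * (len(header) - len(cells))
            rows.append(cells[: len(header)])
        if header is None:
            raise SchemaError(f"sheet {sheet!r} of {path} is empty; no header row")
        return DataTable(header, rows)
    finally:
        book.close()


def read_csv(
    path: str | Path,
    delimiter: str = ",",
    comment_prefix: str | None = None,
) -> DataTable:
    """Read a delimited text file, skipping a leading comment block.

    Comment stripping applies only to the contiguous leading block: a leading
    line starting with ``comment_prefix`` is dropped *unless* it already
    splits into two or more delimited fields — which protects headers whose
    first cell happens to start with the prefix (``#PROTEIN ID``).  Inside
    the data block, lines starting with the prefix are dropped wherever they
    occur; there the ≥2-field exception no longer applies because the header
    has been seen.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    header: list[str] | None = None
    rows: list[list[Cell]] = []
    with open(path, newline="", encoding="utf-8") as handle:
        reader = csv.reader(handle, delimiter=delimiter)
        for lineno, record in enumerate(reader, start=1):
            line_text = delimiter.join(record)
            if header is None:
                if not record or line_text.strip() == "":
                    continue
                if comment_prefix and line_text.startswith(comment_prefix) and len(record) < 2:
                    continue
                header = record
                continue
            if not record or line_text.strip() == "":
                continue
            if comment_prefix and line_text.startswith(comment_prefix):
                continue
            if len(record) != len(header):
                raise SchemaError(
                    f"{path}:{lineno}: row has {len(record)} fields, header has {len(header)}"
                )
            rows.append([parse_cell(cell) for cell in record])
    if header is None:
        raise SchemaError(f"{path}: no header line found after comment stripping")
    return DataTable(header, rows)


def read_mztab(path: str | Path, section: str) -> DataTable:
    """Read one section (PRT, PEP, PSM, or SML) of an mzTab file.

    Lines are dispatched on their first tab-separated token: MTD and COM
    lines are ignored, the section's header line (PRH/PEH/PSH/SMH) supplies
    the column names with the row-type token dropped, and the matching data
    lines become rows in file order.  Optional columns are kept verbatim.
    The same token rule accepts both mzTab 1.0 and mzTab-M 2.0 small-molecule
    sections.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    section = section.upper()
    if section not in MZTAB_SECTIONS:
        raise SelectorError(
            f"unknown mzTab section {section!r}; choose one of {sorted(MZTAB_SECTIONS)}"
        )
    header_token = MZTAB_SECTIONS[section]
    header: list[str] | None = None
    rows: list[list[Cell]] = []
    found_sections: set[str] = set()
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            token = fields[0]
            if token in MZTAB_SECTIONS:
                found_sections.add(token)
            if token == header_token:
                header = fields[1:]
            elif token == section:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: {section} data line before its "
                        f"{header_token} header line"
                    )
                cells = fields[1:]
                if len(cells) < len(header):
                    cells += [""] * (len(header) - len(cells))
                # "null" is mzTab's explicit missing-value marker
                rows.append(
                    [None if c == "null" else parse_cell(c) for c in cells[: len(header)]]
                )
            # MTD, COM, other sections' lines: ignored
    if header is None:
        raise SelectorError(
            f"section {section} not found in {path}; sections found: "
            + (", ".join(sorted(found_sections)) if found_sections else "none")
        )
    return DataTable(header, rows)


def _format_cell(value: Cell) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_table(table: DataTable, path: str | Path, format: str = "xlsx") -> None:
    """Write header plus data rows; the matching reader reproduces the table."""
    path = Path(path)
    try:
        if format == "xlsx":
            book = openpyxl.Workbook()
            ws = book.active
            ws.title = "filtered"
            ws.append(table.columns)
            for row in table.rows:
                ws.append(row)
            book.save(path)
        elif format == "tsv":
            with open(path, "w", newline="", encoding="utf-8") as handle:
                writer = csv.writer(handle, delimiter="\t")
                writer.writerow(table.columns)
                for row in table.rows:
                    writer.writerow([_format_cell(c) for c in row])
        else:
            raise OutputError(f"unsupported output format: {format!r}")
    except OSError as exc:
        raise OutputError(f"cannot write {path}: {exc}") from exc


@dataclass(frozen=True)
class SourceSpec:
    """Where a table comes from: path, format, and the in-file selector.

    The selector is the sheet name for xlsx and the section (PRT, PEP, PSM,
    or SML) for mzTab; CSV takes no selector but allows a delimiter and a
    leading comment prefix.
    """

    path: str
    format: str  # xlsx | csv | mztab
    selector: str | None = None
    delimiter: str = ","
    comment_prefix: str | None = None

    def __post_init__(self) -> None:
        if self.format in ("xlsx", "mztab") and not self.selector:
            raise SelectorError(f"{self.format} source requires a selector (sheet/section)")
        if self.format == "csv" and self.selector is not None:
            raise SelectorError("csv source takes no selector")
        if self.format not in ("xlsx", "csv", "mztab"):
            raise SelectorError(f"unknown input format: {self.format!r}")


def read(spec: SourceSpec) -> DataTable:
    """Read the table a :class:`SourceSpec` points at."""
    return read_source(
        spec.path,
        spec.format,
        sheet=spec.selector if spec.format == "xlsx" else None,
        section=spec.selector if spec.format == "mztab" else None,
        delimiter=spec.delimiter,
        comment_prefix=spec.comment_prefix,
    )


def read_source(
    path: str | Path,
    format: str,
    *,
    sheet: str | None = None,
    section: str | None = None,
    delimiter: str = ",",
    comment_prefix: str | None = None,
) -> DataTable:
    """Dispatch to the reader matching ``format`` (xlsx | csv | mztab)."""
    if format == "xlsx":
        if sheet is None:
            raise SelectorError("xlsx input requires a sheet name")
        return read_xlsx(path, sheet)
    if format == "csv":
        return read_csv(path, delimiter=delimiter, comment_prefix=comment_prefix)
    if format == "mztab":
        if section is None:
            raise SelectorError("mzTab input requires a section (PRT, PEP, PSM, or SML)")
        return read_mztab(path, section)
    raise SelectorError(f"unknown input format: {format!r}")
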