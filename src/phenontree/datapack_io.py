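"""Reading and writing the tab-delimited evolutionary-tree datapack dialect.

A datapack is a tab-delimited text file in which each data row carries the
cells of spreadsheet columns B..K.  Column A (the first tab field) exists in
spreadsheet-derived exports but carries no data; data begins at field 2.
Three row kinds occur in an evolutionary-tree column:

* range-point rows — ``Label (B), Age in Ma (C), Abundance (D), Pop-up (E)``;
  one dated point of a taxon's time range, styled from this point toward the
  next younger point;
* branch rows — ``Parent-name (B), Age (C), "branch" (D), Child-name (E),
  on/off (F), BranchLabel (G), Dashed/Dotted (H), Pop-up (I), BranchColor (J),
  Priority (K)``; a descendant originating from its parent at the given age;
* phenon TOP rows — ``Label (B), Age (C), "TOP" (D), Pop-up (E), blank (F),
  "phenon" (G), Species-name (H)``; the last-appearance point of a phenon
  range, flagged as a phenon and naming the species box in which the range
  ends.  This single linking entry is all that couples the two trees.

The dialect accepts an optional one-line header ``<column name>\\t
evolutionary-tree``; headerless files get a default column name.  Ages are
decimal Ma (millions of years before present, larger = older, 0 = present).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

__all__ = [
    "RowKind",
    "DataRow",
    "Datapack",
    "DatapackParseError",
    "ParseIssue",
    "parse_datapack",
    "write_datapack",
    "split_display_label",
]

#: number of carried spreadsheet cells, columns B..K inclusive
N_CELLS = 10

#: cell indices within DataRow.cells (cells[0] == column B)
COL_B, COL_C, COL_D, COL_E, COL_F, COL_G, COL_H, COL_I, COL_J, COL_K = range(N_CELLS)

DEFAULT_COLUMN_NAME = "evolutionary-tree"
COLUMN_TYPE_TAG = "evolutionary-tree"


class RowKind(enum.Enum):
    RANGE_POINT = "range_point"
    BRANCH = "branch"
    PHENON_TOP = "phenon_top"


@dataclass(frozen=True)
class DataRow:
    """One classified data row; ``cells`` are the raw texts of columns B..K."""

    kind: RowKind
    cells: tuple[str, ...]
    line_number: int = 1

    def __post_init__(self) -> None:
        if len(self.cells) != N_CELLS:
            padded = tuple(self.cells[:N_CELLS]) + ("",) * (N_CELLS - len(self.cells))
            object.__setattr__(self, "cells", padded)

    @property
    def label(self) -> str:
        return self.cells[COL_B]

    @property
    def age(self) -> float:
        return float(self.cells[COL_C])

    def structurally_equals(self, other: "DataRow") -> bool:
        return self.kind is other.kind and self.cells == other.cells


@dataclass
class Datapack:
    column_name: str = DEFAULT_COLUMN_NAME
    rows: list[DataRow] = field(default_factory=list)
    source_path: str | None = None

    def structurally_equals(self, other: "Datapack") -> bool:
        return (
            self.column_name == other.column_name
            and len(self.rows) == len(other.rows)
            and all(a.structurally_equals(b) for a, b in zip(self.rows, other.rows))
        )


@dataclass(frozen=True)
class ParseIssue:
    line_number: int
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"line {self.line_number}: {self.message}"


class DatapackParseError(ValueError):
    """Raised when one or more rows cannot be classified or parsed."""

    def __init__(self, issues: list[ParseIssue]):
        self.issues = issues
        super().__init__("; ".join(str(i) for i in issues))


def _is_number(text: str) -> bool:
    try:
        float(text)
    except ValueError:
        return False
    return True


def _classify(cells: tuple[str, ...], line_number: int) -> DataRow:
    b, c, d = cells[COL_B], cells[COL_C], cells[COL_D]
    if d.strip().lower() == "branch":
        if not cells[COL_E]:
            raise DatapackParseError(
                [ParseIssue(line_number, "branch row without a child name (column E)")]
            )
        if not _is_number(c):
            raise DatapackParseError(
                [ParseIssue(line_number, f"branch age {c!r} (column C) is not numeric")]
            )
        return DataRow(RowKind.BRANCH, cells, line_number)
    if d.strip().upper() == "TOP" and cells[COL_G].strip().lower() == "phenon":
        if not cells[COL_H]:
            raise DatapackParseError(
                [ParseIssue(line_number, "phenon TOP row without a species name (column H)")]
            )
        if not b:
            raise DatapackParseError([ParseIssue(line_number, "phenon TOP row without a label")])
        if not _is_number(c):
            raise DatapackParseError(
                [ParseIssue(line_number, f"age {c!r} (column C) is not numeric")]
            )
        return DataRow(RowKind.PHENON_TOP, cells, line_number)
    # everything else must be a plain range point
    if not b:
        raise DatapackParseError(
            [ParseIssue(line_number, "row has no label (column B) and is not a branch")]
        )
    if not _is_number(c):
        raise DatapackParseError(
            [ParseIssue(line_number, f"age {c!r} (column C) is not numeric")]
        )
    if float(c) < 0:
        raise DatapackParseError([ParseIssue(line_number, f"age {c} is negative")])
    return DataRow(RowKind.RANGE_POINT, cells, line_number)


def parse_datapack(text: str, source_path: str | None = None) -> Datapack:
    """Parse datapack text into a :class:`Datapack`.

    Blank lines and ``#`` comment lines are permitted anywhere.  Row order is
    preserved.  All unparseable rows are collected and reported together in a
    single :class:`DatapackParseError` naming their line numbers.  An empty
    input yields an empty datapack.
    """
    column_name = DEFAULT_COLUMN_NAME
    rows: list[DataRow] = []
    issues: list[ParseIssue] = []
    seen_header = False
    seen_data = False
    for line_number, raw in enumerate(text.splitlines(), start=1):
        if not raw.strip() or raw.lstrip().startswith("#"):
            continue
        fields = raw.split("\t")
        if not seen_header and not seen_data:
            # optional one-line header: "<column name>\tevolutionary-tree"
            if len(fields) >= 2 and fields[1].strip().lower() == COLUMN_TYPE_TAG and fields[0].strip():
                column_name = fields[0].strip()
                seen_header = True
                continue
        seen_data = True
        cells = tuple((fields[1:] + [""] * N_CELLS)[:N_CELLS])
        cells = tuple(c.strip() for c in cells)
        try:
            rows.append(_classify(cells, line_number))
        except DatapackParseError as err:
            issues.extend(err.issues)
    if issues:
        raise DatapackParseError(issues)
    return Datapack(column_name=column_name, rows=rows, source_path=source_path)


def write_datapack(pack: Datapack) -> str:
    """Serialize a datapack; ``parse_datapack(write_datapack(p))`` is the
    structural identity.  Trailing empty cells are omitted per row."""
    lines = [f"{pack.column_name}\t{COLUMN_TYPE_TAG}"]
    for row in pack.rows:
        cells = list(row.cells)
        while cells and cells[-1] == "":
            cells.pop()
        lines.append("\t" + "\t".join(cells))
    return "\n".join(lines) + "\n"


def split_display_label(name: str) -> tuple[str, str]:
    """Short phenon labels: ``"bullbrooki | Bolli, 1957; Globorotalia"`` is
    displayed as ``"bullbrooki"``.

    Returns ``(display, full)``.  If ``name`` contains ``"|"`` the display
    label is the text before the first ``"|"`` with surrounding whitespace
    trimmed; otherwise display and full name coincide.
    """
    if "|" in name:
        return name.split("|", 1)[0].strip(), name
    return name, name


def with_source(pack: Datapack, path: str) -> Datapack:
    return replace(pack, source_path=path)
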