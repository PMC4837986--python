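"""Readers and writers for submission and gold-standard file dialects.

All formats are plain text: tab- or comma-separated edge lists, CSV
prediction tables with an id column, a block format for position weight
matrices, and a small CSV layout for survival records.  Readers validate on
load and every validation error carries the file position (line number,
block name, column index) of the offending record; readers never mutate
their input files.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import FormatError, ValidationError
from .metrics import SurvivalRecord
from .pwm import PWMatrix, normalize_columns

__all__ = [
    "RankedEdgeList",
    "PredictionTable",
    "read_edge_list",
    "write_edge_list",
    "read_multi_edge_list",
    "write_multi_edge_list",
    "read_prediction_table",
    "write_prediction_table",
    "read_pwm_file",
    "write_pwm_file",
    "read_survival_table",
    "write_survival_table",
]

#: renormalize a PWM column whose sum is off by at most this much (warn)
PWM_RENORM_TOL = 1e-3
#: accept a PWM column silently when its sum is within this of 1
PWM_EXACT_TOL = 1e-6


# ---------------------------------------------------------------------------
# ranked edge lists
# ---------------------------------------------------------------------------

@dataclass
class RankedEdgeList:
    """An ordered list of candidate network edges with confidences.

    After construction the edges are sorted by descending confidence with a
    stable sort, so ties keep their original (file) order.  Duplicate
    (source, target) pairs are rejected.
    """

    edges: list  # list of (source, target, confidence)
    node_universe: frozenset | None = field(default=None)

    def __post_init__(self) -> None:
        seen = {}
        cleaned = []
        for k, (s, t, c) in enumerate(self.edges):
            c = float(c)
            if not math.isfinite(c):
                raise ValidationError(f"edge ({s},{t}): non-finite confidence {c!r}")
            if (s, t) in seen:
                raise ValidationError(
                    f"duplicate edge ({s},{t}) at positions {seen[(s, t)]} and {k}"
                )
            seen[(s, t)] = k
            cleaned.append((s, t, c))
        cleaned.sort(key=lambda e: -e[2])  # stable: ties keep input order
        object.__setattr__(self, "edges", cleaned)
        if self.node_universe is not None:
            object.__setattr__(self, "node_universe", frozenset(self.node_universe))

    def __len__(self) -> int:
        return len(self.edges)

    @property
    def edge_pairs(self) -> list:
        return [(s, t) for s, t, _ in self.edges]

    @property
    def nodes(self) -> frozenset:
        return frozenset(n for s, t, _ in self.edges for n in (s, t))


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def _parse_edge_lines(
    numbered_lines, origin: str, delimiter: str | None, directed: bool
) -> RankedEdgeList:
    edges = []
    seen = {}
    for lineno, line in numbered_lines:
        if delimiter is None:
            delimiter = _detect_delimiter(line)
        fields = [f.strip() for f in line.split(delimiter)]
        if len(fields) != 3:
            raise FormatError(
                f"{origin}:{lineno}: expected 3 fields "
                f"(source, target, confidence), got {len(fields)}"
            )
        s, t, c_raw = fields
        try:
            c = float(c_raw)
        except ValueError:
            raise FormatError(
                f"{origin}:{lineno}: non-numeric confidence {c_raw!r}"
            ) from None
        if not math.isfinite(c):
            raise FormatError(f"{origin}:{lineno}: non-finite confidence {c_raw!r}")
        if not directed:
            s, t = min(s, t), max(s, t)
        if (s, t) in seen:
            raise FormatError(
                f"{origin}:{lineno}: duplicate edge ({s},{t}), "
                f"first seen on line {seen[(s, t)]}"
            )
        seen[(s, t)] = lineno
        edges.append((s, t, c))
    if not edges:
        raise FormatError(f"{origin}: empty edge list")
    return RankedEdgeList(edges=edges)


def read_edge_list(
    path, *, delimiter: str | None = None, directed: bool = True
) -> RankedEdgeList:
    """Parse a 3-column (source, target, confidence) edge list.

    The delimiter (tab vs comma) is auto-detected from the first data line
    unless forced.  In undirected mode each pair is canonicalized to
    (min, max) before the duplicate check.
    """
    path = Path(path)
    numbered = [
        (lineno, line.strip())
        for lineno, line in enumerate(path.read_text().splitlines(), start=1)
        if line.strip() and not line.strip().startswith("#")
    ]
    return _parse_edge_lines(numbered, str(path), delimiter, directed)


def write_edge_list(edge_list: RankedEdgeList, path, *, delimiter: str = "\t") -> None:
    lines = [
        f"{s}{delimiter}{t}{delimiter}{c:.12g}" for s, t, c in edge_list.edges
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_multi_edge_list(
    path, *, delimiter: str | None = None, directed: bool = True
) -> dict:
    """Parse a file of named '> name' blocks, each a 3-column edge list.

    Used by the multi-network challenges whose submission bundles one
    ranked edge list per data set.  Returns ``{name: RankedEdgeList}`` in
    file order.
    """
    path = Path(path)
    blocks: dict[str, list] = {}
    current = None
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            current = line[1:].strip()
            if not current:
                raise FormatError(f"{path}:{lineno}: empty block name")
            if current in blocks:
                raise FormatError(f"{path}:{lineno}: duplicate block {current!r}")
            blocks[current] = []
        else:
            if current is None:
                raise FormatError(
                    f"{path}:{lineno}: edge line before any '> name' header"
                )
            blocks[current].append((lineno, line))
    if not blocks:
        raise FormatError(f"{path}: no '> name' blocks found")
    return {
        name: _parse_edge_lines(lines, f"{path}[{name}]", delimiter, directed)
        for name, lines in blocks.items()
    }


def write_multi_edge_list(named_lists: dict, path, *, delimiter: str = "\t") -> None:
    parts = []
    for name, el in named_lists.items():
        parts.append(f"> {name}")
        parts.extend(f"{s}{delimiter}{t}{delimiter}{c:.12g}" for s, t, c in el.edges)
    Path(path).write_text("\n".join(parts) + "\n")


# ---------------------------------------------------------------------------
# prediction tables
# ---------------------------------------------------------------------------

@dataclass
class PredictionTable:
    """A rectangular table of real values with row and column ids."""

    row_ids: list
    column_ids: list
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.row_ids), len(self.column_ids)):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{len(self.row_ids)} rows x {len(self.column_ids)} columns"
            )
        if len(set(self.row_ids)) != len(self.row_ids):
            raise ValidationError("duplicate row ids")
        if len(set(self.column_ids)) != len(self.column_ids):
            raise ValidationError("duplicate column ids")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "row_ids", list(self.row_ids))
        object.__setattr__(self, "column_ids", list(self.column_ids))

    @property
    def shape(self) -> tuple:
        return self.values.shape


def read_prediction_table(path, expected_shape: tuple | None = None) -> PredictionTable:
    """Read a CSV with a header row and a leading id column."""
    import csv

    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if len(rows) < 2:
        raise FormatError(f"{path}: need a header row and at least one data row")
    header = rows[0]
    column_ids = [c.strip() for c in header[1:]]
    width = len(header)
    row_ids, values = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != width:
            raise FormatError(
                f"{path}:{lineno}: ragged row ({len(row)} fields, header has {width})"
            )
        rid = row[0].strip()
        row_ids.append(rid)
        parsed = []
        for col_id, cell in zip(column_ids, row[1:]):
            cell = cell.strip()
            if cell == "":
                raise FormatError(
                    f"{path}:{lineno}: missing cell at row {rid!r}, column {col_id!r}"
                )
            try:
                parsed.append(float(cell))
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric value {cell!r} at row {rid!r}, "
                    f"column {col_id!r}"
                ) from None
        values.append(parsed)
    try:
        table = PredictionTable(row_ids, column_ids, np.array(values, dtype=float))
    except ValidationError as err:
        raise FormatError(f"{path}: {err}") from None
    if expected_shape is not None and table.shape != tuple(expected_shape):
        raise FormatError(
            f"{path}: shape {table.shape} does not match expected "
            f"{tuple(expected_shape)}"
        )
    return table


def write_prediction_table(table: PredictionTable, path, *, id_label: str = "id") -> None:
    """Write a table as CSV with 12 significant digits (round-trip safe)."""
    lines = [",".join([id_label, *map(str, table.column_ids)])]
    for rid, row in zip(table.row_ids, table.values):
        lines.append(",".join([str(rid), *(f"{v:.12g}" for v in row)]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PWM block files
# ---------------------------------------------------------------------------

def read_pwm_file(path) -> list:
    """Parse a text file of named PWM blocks.

    A block is a ``> name`` line followed by one whitespace-separated row of
    reals per symbol.  Column sums are validated: within 1e-6 of 1 the
    column is accepted, within 1e-3 it is renormalized with a warning,
    otherwise the block and column are named in the error.
    """
    path = Path(path)
    blocks: list[tuple[str, list]] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].strip()
            if not name:
                raise FormatError(f"{path}:{lineno}: empty PWM block name")
            blocks.append((name, []))
        else:
            if not blocks:
                raise FormatError(f"{path}:{lineno}: row before any '> name' header")
            try:
                row = [float(x) for x in line.split()]
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-numeric PWM entry in block "
                    f"{blocks[-1][0]!r}"
                ) from None
            blocks[-1][1].append(row)
    if not blocks:
        raise FormatError(f"{path}: no PWM blocks found")
    matrices = []
    for name, rows in blocks:
        if not rows:
            raise FormatError(f"{path}: block {name!r} has no rows")
        widths = {len(r) for r in rows}
        if len(widths) != 1:
            raise FormatError(f"{path}: block {name!r} has ragged rows")
        values = np.array(rows, dtype=float)
        sums = values.sum(axis=0)
        off = np.abs(sums - 1.0)
        bad = np.flatnonzero(off > PWM_RENORM_TOL)
        if bad.size:
            j = int(bad[0])
            raise FormatError(
                f"{path}: block {name!r}, column {j}: sum {sums[j]:.6g} is off "
                f"by more than {PWM_RENORM_TOL}"
            )
        if np.any(off > PWM_EXACT_TOL):
            warnings.warn(
                f"{path}: block {name!r}: renormalized column(s) "
                f"{np.flatnonzero(off > PWM_EXACT_TOL).tolist()} "
                f"(sums within {PWM_RENORM_TOL} of 1)",
                UserWarning,
                stacklevel=2,
            )
            values = normalize_columns(values)
        else:
            values = normalize_columns(values)  # exact simplex for downstream checks
        matrices.append(PWMatrix(values=values, name=name))
    return matrices


def write_pwm_file(matrices: Sequence[PWMatrix], path) -> None:
    parts = []
    for m in matrices:
        parts.append(f"> {m.name or 'pwm'}")
        for row in m.values:
            parts.append(" ".join(f"{v:.12g}" for v in row))
    Path(path).write_text("\n".join(parts) + "\n")


# ---------------------------------------------------------------------------
# survival tables
# ---------------------------------------------------------------------------

_EVENT_VALUES = {"0": 0, "1": 1, "TRUE": 1, "FALSE": 0}


def read_survival_table(path) -> list:
    """Read a CSV with columns time, event, risk (fixed header names)."""
    import csv

    path = Path(path)
    with path.open(newline="") as fh:
        rows = list(csv.reader(fh))
    rows = [r for r in rows if any(cell.strip() for cell in r)]
    if len(rows) < 2:
        raise FormatError(f"{path}: empty survival table")
    header = [h.strip().lower() for h in rows[0]]
    try:
        idx = {name: header.index(name) for name in ("time", "event", "risk")}
    except ValueError:
        raise FormatError(
            f"{path}: header must contain columns time, event, risk; got {header}"
        ) from None
    records = []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise FormatError(f"{path}:{lineno}: ragged row")
        try:
            time = float(row[idx["time"]])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric time {row[idx['time']]!r}"
            ) from None
        event_raw = row[idx["event"]].strip().upper()
        if event_raw not in _EVENT_VALUES:
            raise FormatError(
                f"{path}:{lineno}: event must be one of 0, 1, TRUE, FALSE; "
                f"got {row[idx['event']]!r}"
            )
        try:
            risk = float(row[idx["risk"]])
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric risk {row[idx['risk']]!r}"
            ) from None
        try:
            records.append(
                SurvivalRecord(time=time, event=_EVENT_VALUES[event_raw], risk=risk)
            )
        except ValidationError as err:
            raise FormatError(f"{path}:{lineno}: {err}") from None
    return records


def write_survival_table(records: Sequence[SurvivalRecord], path) -> None:
    lines = ["time,event,risk"]
    lines.extend(f"{r.time:.12g},{r.event},{r.risk:.12g}" for r in records)
    Path(path).write_text("\n".join(lines) + "\n")
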