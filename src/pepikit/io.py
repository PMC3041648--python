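"""File input/output and the session results log.

Summary tables travel as small UTF-8 CSV or TSV files (delimiter sniffed,
header row optional): a 2x2 table as a single row ``a,b,c,d`` or a 2x2
grid; stratified tables as rows ``stratum,a,b,c,d``; an ordered 2xk table
as two rows of counts; rating matrices as n rows x m columns; paired
numeric data as two columns; grouped numeric data as one column per group;
stratum counts as ``label,events,denominator``; standard populations as
``label,weight``.

Every CLI invocation appends a self-contained, timestamped entry to a
plain-text session log (default ``pepikit.log`` in the working directory),
so a session's results can be reviewed afterwards.
"""

from __future__ import annotations

import datetime as _dt
import io as _io
import os
from pathlib import Path

import numpy as np

from .tables import (
    GroupedNumericSamples,
    OrderedTwoByK,
    PairedNumericSeries,
    RatingMatrix,
    RxCTable,
    StandardPopulation,
    StratifiedTwoByTwo,
    StratumCounts,
    TwoByTwoTable,
)

TABLE_KINDS = (
    "two_by_two",
    "rxc",
    "ordered_two_by_k",
    "stratified",
    "ratings",
    "paired_numeric",
    "grouped_numeric",
    "stratum_counts",
    "standard_population",
)


def _sniff_delimiter(text: str) -> str:
    first = next((line for line in text.splitlines() if line.strip()), "")
    return "\t" if first.count("\t") >= first.count(",") and "\t" in first else ","


def _is_number(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


def _parse_rows(path) -> list[tuple[int, list[str]]]:
    text = Path(path).read_text(encoding="utf-8")
    delim = _sniff_delimiter(text)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        rows.append((lineno, [tok.strip() for tok in line.split(delim)]))
    if not rows:
        raise ValueError(f"{path}: file is empty")
    # drop a header row (any fully non-numeric row at the top)
    if all(not _is_number(tok) for tok in rows[0][1] if tok):
        rows = rows[1:]
    if not rows:
        raise ValueError(f"{path}: no data rows")
    return rows


def _numeric(rows, path, *, skip_first_col: bool = False):
    out = []
    for lineno, tokens in rows:
        values = tokens[1:] if skip_first_col else tokens
        try:
            out.append([float(v) for v in values if v != ""])
        except ValueError as exc:
            raise ValueError(f"{path}, line {lineno}: non-numeric value ({exc})") from None
    return out


def read_table_file(path, expected_kind: str):
    """Read and validate a summary-data file of the expected kind."""
    if expected_kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {expected_kind!r}; choose from {TABLE_KINDS}")
    rows = _parse_rows(path)

    if expected_kind == "two_by_two":
        data = _numeric(rows, path)
        if len(data) == 1 and len(data[0]) == 4:
            a, b, c, d = data[0]
        elif len(data) == 2 and all(len(r) == 2 for r in data):
            (a, b), (c, d) = data
        else:
            raise ValueError(f"{path}: expected one row a,b,c,d or a 2x2 grid")
        return TwoByTwoTable(a, b, c, d)

    if expected_kind == "rxc":
        data = _numeric(rows, path)
        widths = {len(r) for r in data}
        if len(widths) != 1:
            raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")
        return RxCTable(np.array(data))

    if expected_kind == "ordered_two_by_k":
        data = _numeric(rows, path)
        if len(data) != 2 or len(data[0]) != len(data[1]):
            raise ValueError(f"{path}: expected exactly two equal-length rows of counts")
        return OrderedTwoByK(tuple(int(v) for v in data[0]), tuple(int(v) for v in data[1]))

    if expected_kind == "stratified":
        strata = []
        for lineno, tokens in rows:
            if len(tokens) != 5:
                raise ValueError(f"{path}, line {lineno}: expected stratum,a,b,c,d")
            label = tokens[0]
            try:
                a, b, c, d = (float(v) for v in tokens[1:])
            except ValueError:
                raise ValueError(f"{path}, line {lineno}: non-numeric cell") from None
            strata.append((label, TwoByTwoTable(a, b, c, d)))
        return StratifiedTwoByTwo(tuple(strata))

    if expected_kind == "ratings":
        data = _numeric(rows, path)
        widths = {len(r) for r in data}
        if len(widths) != 1:
            raise ValueError(f"{path}: ragged rating rows")
        return RatingMatrix(np.array(data))

    if expected_kind == "paired_numeric":
        data = _numeric(rows, path)
        if any(len(r) != 2 for r in data):
            raise ValueError(f"{path}: expected two columns (x, y)")
        arr = np.array(data)
        return PairedNumericSeries(arr[:, 0], arr[:, 1])

    if expected_kind == "grouped_numeric":
        data = _numeric(rows, path)
        width = max(len(r) for r in data)
        columns = [[] for _ in range(width)]
        for _, tokens in rows:
            for j, tok in enumerate(tokens):
                if tok != "":
                    columns[j].append(float(tok))
        return GroupedNumericSamples(tuple(np.array(col) for col in columns if col))

    if expected_kind == "stratum_counts":
        labels, events, denoms = [], [], []
        for lineno, tokens in rows:
            if len(tokens) != 3:
                raise ValueError(f"{path}, line {lineno}: expected label,events,denominator")
            labels.append(tokens[0])
            try:
                events.append(float(tokens[1]))
                denoms.append(float(tokens[2]))
            except ValueError:
                raise ValueError(f"{path}, line {lineno}: non-numeric value") from None
        return StratumCounts(tuple(labels), tuple(events), tuple(denoms))

    # standard_population
    labels, weights = [], []
    for lineno, tokens in rows:
        if len(tokens) != 2:
            raise ValueError(f"{path}, line {lineno}: expected label,weight")
        labels.append(tokens[0])
        try:
            weights.append(float(tokens[1]))
        except ValueError:
            raise ValueError(f"{path}, line {lineno}: non-numeric weight") from None
    return StandardPopulation(Path(path).stem, tuple(labels), tuple(weights))


def write_table_file(obj, path) -> None:
    """Write a summary-data object in the CSV dialect `read_table_file` reads."""
    buf = _io.StringIO()
    if isinstance(obj, TwoByTwoTable):
        buf.write(",".join(_fmt(v) for v in obj.cells) + "\n")
    elif isinstance(obj, StratifiedTwoByTwo):
        for label, t in obj.strata:
            buf.write(",".join([label] + [_fmt(v) for v in t.cells]) + "\n")
    elif isinstance(obj, OrderedTwoByK):
        buf.write(",".join(str(v) for v in obj.row1) + "\n")
        buf.write(",".join(str(v) for v in obj.row2) + "\n")
    elif isinstance(obj, RxCTable):
        for row in obj.counts:
            buf.write(",".join(_fmt(v) for v in row) + "\n")
    elif isinstance(obj, RatingMatrix):
        for row in obj.ratings:
            buf.write(",".join(_fmt(v) for v in row) + "\n")
    elif isinstance(obj, PairedNumericSeries):
        for x, y in zip(obj.x, obj.y):
            buf.write(f"{float(x)!r},{float(y)!r}\n")
    elif isinstance(obj, StratumCounts):
        for label, e, d in zip(obj.labels, obj.events, obj.denominators):
            buf.write(f"{label},{_fmt(e)},{_fmt(d)}\n")
    elif isinstance(obj, StandardPopulation):
        for label, w in zip(obj.labels, obj.weights):
            buf.write(f"{label},{_fmt(w)}\n")
    else:
        raise TypeError(f"cannot serialize {type(obj).__name__}")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _fmt(v: float) -> str:
    return str(int(v)) if float(v).is_integer() else repr(float(v))


class SessionLog:
    """Append-only plain-text log of analysis results.

    Each entry is self-contained: an ISO-8601 timestamp, the subcommand,
    an echo of the inputs, the full results block, and an optional user
    comment, delimited by marker lines.  Entries are written with a single
    append call so concurrent invocations do not interleave within one
    entry.
    """

    ENTRY_START = "=== pepikit entry"
    ENTRY_END = "=== end entry ==="

    def __init__(self, path: str | os.PathLike = "pepikit.log") -> None:
        self.path = Path(path)

    def append(self, subcommand: str, inputs: str, results: str,
               comment: str | None = None) -> None:
        stamp = _dt.datetime.now().isoformat(timespec="seconds")
        lines = [f"{self.ENTRY_START} {stamp} ===",
                 f"command: {subcommand}",
                 f"inputs: {inputs}",
                 "results:"]
        lines += ["  " + line for line in results.rstrip("\n").splitlines()]
        if comment:
            lines.append(f"comment: {comment}")
        lines.append(self.ENTRY_END)
        with open(self.path, "a", encoding="utf-8") as handle:
            handle.write("\n".join(lines) + "\n")

    def entries(self) -> list[dict]:
        """Re-parse the log into its entries."""
        if not self.path.exists():
            return []
        out = []
        current: dict | None = None
        in_results = False
        for line in self.path.read_text(encoding="utf-8").splitlines():
            if line.startswith(self.ENTRY_START):
                stamp = line[len(self.ENTRY_START):].strip().rstrip("=").strip()
                current = {"timestamp": stamp, "command": "", "inputs": "",
                           "results": [], "comment": None}
                in_results = False
            elif current is None:
                continue
            elif line == self.ENTRY_END:
                current["results"] = "\n".join(current["results"])
                out.append(current)
                current = None
            elif line.startswith("command: "):
                current["command"] = line[len("command: "):]
            elif line.startswith("inputs: "):
                current["inputs"] = line[len("inputs: "):]
            elif line == "results:":
                in_results = True
            elif line.startswith("comment: "):
                current["comment"] = line[len("comment: "):]
                in_results = False
            elif in_results and line.startswith("  "):
                current["results"].append(line[2:])
        return out
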