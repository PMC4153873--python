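"""Publication-ready table assembly and RTF/text output.

Two formats mirror the table styles common in life-science journals:

* ``per_group_sem`` — each cell shows "mean ± SEM" with superscript
  letters from the multiple-comparison result;
* ``pooled_sem`` — cells show the mean only and an extra column carries
  one pooled SEM (sqrt(MSE/n)) per response row.

Rows whose letter display has a single class (no pair significant) carry
no superscripts.  Rounding is half-away-from-zero, applied only at this
display layer; all upstream arithmetic is double precision.

The RTF writer emits a minimal RTF 1.x document (one table, bold header,
``\\super`` letters, footnote paragraph) whose bytes are a pure function of
the TableSpec, so identical inputs give identical files.  A minimal reader
(:func:`read_rtf_cells`) recovers the cell texts for round-trip checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

from .anova import AnovaResult, ResponseSummary
from .cld import LetterDisplay
from .posthoc import MCPResult

__all__ = [
    "TableCell",
    "TableRow",
    "TableSpec",
    "build_table",
    "format_value",
    "write_rtf",
    "write_text",
    "read_rtf_cells",
]


@dataclass(frozen=True)
class TableCell:
    text: str          # e.g. "110 ± 4"
    letters: str = ""  # superscript letters, "" for none


@dataclass(frozen=True)
class TableRow:
    variable: str
    cells: tuple[TableCell, ...]
    pooled_sem: Optional[str] = None


@dataclass(frozen=True)
class TableSpec:
    title: str
    group_headers: tuple[str, ...]
    rows: tuple[TableRow, ...]
    mode: str  # "per_group_sem" | "pooled_sem"
    footnote: str

    def __post_init__(self):
        for row in self.rows:
            if len(row.cells) != len(self.group_headers):
                raise ValueError(
                    f"row {row.variable!r} has {len(row.cells)} cells for "
                    f"{len(self.group_headers)} group columns")


def format_value(value: float, precision: int) -> str:
    """Fixed-point text at ``precision`` decimals, rounding half away from zero."""
    if precision < 0:
        raise ValueError("precision must be >= 0")
    quantum = Decimal(1).scaleb(-precision)
    return str(Decimal(repr(float(value))).quantize(quantum, rounding=ROUND_HALF_UP))


def build_table(results: Sequence[tuple[ResponseSummary, AnovaResult, MCPResult, LetterDisplay]],
                mode: str = "per_group_sem", alpha: float = 0.05,
                test_name: str = "", title: str = "",
                precision: Optional[int] = None) -> TableSpec:
    """Assemble a TableSpec from per-response analysis results.

    ``precision`` overrides the per-group display precision when given;
    otherwise each group's cell echoes its source precision (summary input)
    or the raw-mode default.  Superscripts are attached only when a row's
    letter display has two or more classes.
    """
    if mode not in ("per_group_sem", "pooled_sem"):
        raise ValueError(f"unknown table mode {mode!r}")
    if not results:
        raise ValueError("nothing to render: no analysis results")
    headers = results[0][0].labels
    rows = []
    for summary, anova, mcp, display in results:
        if summary.labels != headers:
            raise ValueError(
                f"inconsistent group labels: {summary.variable!r} has "
                f"{summary.labels}, expected {headers}")
        lettered = len(display.partition) >= 2
        cells = []
        for g, letters in zip(summary.groups, display.letters):
            prec = precision if precision is not None else g.display_precision
            mean_text = format_value(g.mean, prec)
            if mode == "per_group_sem":
                text = f"{mean_text} ± {format_value(g.sem, prec)}"
            else:
                text = mean_text
            cells.append(TableCell(text=text, letters=letters if lettered else ""))
        pooled = None
        if mode == "pooled_sem":
            prec = precision if precision is not None else max(
                g.display_precision for g in summary.groups)
            pooled = format_value(anova.pooled_sem, prec)
        rows.append(TableRow(variable=summary.variable, cells=tuple(cells),
                             pooled_sem=pooled))
    alpha_text = format_value(alpha, 2) if alpha < 0.1 else str(alpha)
    footnote = (f"Means in a row without a common superscript letter differ "
                f"(P < {alpha_text}), as analyzed by one-way ANOVA")
    if test_name:
        footnote += f" followed by the {test_name} test"
    footnote += "."
    return TableSpec(title=title, group_headers=tuple(headers),
                     rows=tuple(rows), mode=mode, footnote=footnote)


# ---------------------------------------------------------------------------
# RTF


def _rtf_escape(text: str) -> str:
    out = []
    for ch in text:
        code = ord(ch)
        if ch in "\\{}":
            out.append("\\" + ch)
        elif code < 128:
            out.append(ch)
        elif code < 256:
            out.append(f"\\'{code:02x}")
        else:
            out.append(f"\\u{code}?")
    return "".join(out)


def _rtf_row(cells: list[str], widths: list[int], bold: bool = False) -> str:
    parts = ["\\trowd\\trgaph108"]
    edge = 0
    for w in widths:
        edge += w
        parts.append(f"\\cellx{edge}")
    for cell in cells:
        body = f"\\b {cell}\\b0" if bold else cell
        parts.append("\\pard\\intbl\\qc {" + body + "}\\cell")
    parts.append("\\row")
    return "".join(parts)


def _cell_rtf(cell: TableCell) -> str:
    text = _rtf_escape(cell.text)
    if cell.letters:
        text += "{\\super " + _rtf_escape(cell.letters) + "}"
    return text


def write_rtf(table: TableSpec, path) -> None:
    """Write the table as a minimal, deterministic RTF 1.x document."""
    if not table.rows:
        raise ValueError("nothing to render")
    n_cols = 1 + len(table.group_headers) + (1 if table.mode == "pooled_sem" else 0)
    widths = [2600] + [1500] * (n_cols - 1)
    lines = ["{\\rtf1\\ansi\\ansicpg1252\\deff0{\\fonttbl{\\f0 Times New Roman;}}",
             "\\fs22"]
    if table.title:
        lines.append("{\\pard\\b " + _rtf_escape(table.title) + "\\b0\\par}")
    header_cells = ["Variable"] + [_rtf_escape(h) for h in table.group_headers]
    if table.mode == "pooled_sem":
        header_cells.append("Pooled SEM")
    lines.append(_rtf_row(header_cells, widths, bold=True))
    for row in table.rows:
        cells = [_rtf_escape(row.variable)] + [_cell_rtf(c) for c in row.cells]
        if table.mode == "pooled_sem":
            cells.append(_rtf_escape(row.pooled_sem or ""))
        lines.append(_rtf_row(cells, widths))
    lines.append("{\\pard " + _rtf_escape(table.footnote) + "\\par}")
    lines.append("}")
    data = "\n".join(lines)
    with open(path, "w", encoding="ascii", newline="\n") as fh:
        fh.write(data)


def read_rtf_cells(path) -> list[list[str]]:
    """Minimal RTF reader: recover the plain cell texts, row by row.

    Understands only what :func:`write_rtf` emits — ``\\cell``/``\\row``
    table structure, ``\\super`` groups (whose text is appended verbatim to
    the cell), ``\\'xx`` byte escapes and ``\\uN?`` unicode escapes.  Meant
    for round-trip verification, not as a general RTF parser.
    """
    with open(path, encoding="ascii") as fh:
        src = fh.read()
    rows: list[list[str]] = []
    current_row: list[str] = []
    buf: list[str] = []
    i = 0
    n = len(src)
    while i < n:
        ch = src[i]
        if ch == "\\":
            i += 1
            if i >= n:
                break
            nxt = src[i]
            if nxt in "\\{}":
                buf.append(nxt)
                i += 1
            elif nxt == "'":
                buf.append(chr(int(src[i + 1:i + 3], 16)))
                i += 3
            else:
                j = i
                while j < n and (src[j].isalpha()):
                    j += 1
                word = src[i:j]
                k = j
                neg = k < n and src[k] == "-"
                if neg:
                    k += 1
                while k < n and src[k].isdigit():
                    k += 1
                param = src[j:k]
                if k < n and src[k] == " ":
                    k += 1
                if word == "u" and param:
                    buf.append(chr(int(param)))
                    if k < n and src[k] == "?":
                        k += 1
                elif word == "pard":
                    buf = []  # paragraph start: drops font-table/title text
                elif word == "cell":
                    current_row.append("".join(buf).strip())
                    buf = []
                elif word == "row":
                    rows.append(current_row)
                    current_row = []
                i = k
        elif ch in "{}\n\r":
            i += 1
        else:
            buf.append(ch)
            i += 1
    return rows


# ---------------------------------------------------------------------------
# text mirrors


def write_text(table: TableSpec, path, dialect: str = "tsv") -> None:
    """Flat text mirror of the table; letters become plain suffixes."""
    if not table.rows:
        raise ValueError("nothing to render")
    if dialect not in ("tsv", "markdown"):
        raise ValueError(f"unknown dialect {dialect!r}")
    header = ["Variable"] + list(table.group_headers)
    if table.mode == "pooled_sem":
        header.append("Pooled SEM")
    body = []
    for row in table.rows:
        cells = [row.variable]
        for c in row.cells:
            cells.append(f"{c.text} {c.letters}" if c.letters else c.text)
        if table.mode == "pooled_sem":
            cells.append(row.pooled_sem or "")
        body.append(cells)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if dialect == "tsv":
            if table.title:
                fh.write(f"# {table.title}\n")
            fh.write("\t".join(header) + "\n")
            for cells in body:
                fh.write("\t".join(cells) + "\n")
            fh.write(f"# {table.footnote}\n")
        else:
            if table.title:
                fh.write(f"**{table.title}**\n\n")
            fh.write("| " + " | ".join(header) + " |\n")
            fh.write("|" + "|".join([" --- "] * len(header)) + "|\n")
            for cells in body:
                fh.write("| " + " | ".join(cells) + " |\n")
            fh.write(f"\n{table.footnote}\n")
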