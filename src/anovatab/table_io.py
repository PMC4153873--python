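"""Reading workbooks and CSV files into analysis-ready dataset bundles.

Four input scenarios are supported:

* ``S1`` — one raw dataset in a single sheet: one factor column plus one
  or more numeric response columns, rows = experimental units.
* ``S2`` — several raw datasets, one per sheet of a workbook.
* ``S3`` — one summary dataset in a single sheet: first column = group
  label, then a (mean, dispersion) column pair per response variable; the
  pair's first header names the response, the second header (e.g. "SEM")
  is not interpreted.  Sample sizes are supplied separately.
* ``S4`` — several summary datasets, one per sheet.

Empty cells are missing values.  The data block does not have to start at
the top-left cell: the rectangular region is located automatically, with a
header row required in its first row.  Two disjoint blocks in one sheet
are an error, never a guess.

Supported formats: ``.xlsx`` workbooks and single-sheet ``.csv`` (UTF-8,
RFC 4180); missing = empty cell or a standard NA token.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

from .anova import GroupSummary, ResponseSummary, is_missing, summarize_raw

__all__ = [
    "DatasetBundle",
    "Workbook",
    "read_workbook",
    "parse_sizes",
    "validate_names",
    "infer_precision",
]

SCENARIOS = ("S1", "S2", "S3", "S4")
RAW_SCENARIOS = ("S1", "S2")
MULTI_SHEET = ("S2", "S4")


@dataclass
class DatasetBundle:
    """One analysis-ready dataset (one sheet's worth of data).

    In raw mode ``factor`` holds the factor column and ``raw_responses``
    maps each response name to its column; ``response_summaries()`` reduces
    them to per-group summaries.  In summary mode ``summaries`` holds one
    ResponseSummary per response, sizes already attached.
    """

    name: str
    mode: str  # "raw" | "summary"
    factor_name: Optional[str] = None
    factor: Optional[list] = None
    raw_responses: dict = field(default_factory=dict)
    summaries: list = field(default_factory=list)
    sizes: Optional[list] = None
    warnings: list = field(default_factory=list)

    @property
    def response_names(self) -> list[str]:
        if self.mode == "raw":
            return list(self.raw_responses)
        return [s.variable for s in self.summaries]

    def response_summaries(self) -> list[ResponseSummary]:
        if self.mode == "summary":
            return list(self.summaries)
        out = []
        for name, col in self.raw_responses.items():
            out.append(summarize_raw(self.factor, col, variable=name,
                                     display_precision=2))
        return out


@dataclass
class Workbook:
    path: str
    scenario: str
    sheets: list  # of DatasetBundle, sheet order preserved


def infer_precision(cell) -> int:
    """Decimal places a cell value was printed with (text-form inference)."""
    text = str(cell).strip()
    if "." in text:
        return len(text.split(".", 1)[1])
    return 0


def parse_sizes(spec: str, n_groups: int) -> list[int]:
    """Parse a sample-size specification.

    A single token is a common (balanced) per-group size, replicated; with
    exactly one token per group the values are assigned positionally, in
    the order the groups appear in the file.
    """
    tokens = str(spec).split()
    if not tokens:
        raise ValueError("sample-size specification is empty")
    if len(tokens) not in (1, n_groups):
        raise ValueError(
            f"expected 1 or {n_groups} sample sizes, got {len(tokens)}")
    sizes = []
    for tok in tokens:
        try:
            val = int(tok)
        except ValueError:
            raise ValueError(f"sample size {tok!r} is not an integer") from None
        if val < 2:
            raise ValueError(f"sample size must be >= 2, got {val}")
        sizes.append(val)
    if len(sizes) == 1:
        sizes = sizes * n_groups
    return sizes


def validate_names(names: Sequence[str]) -> list[tuple[str, str, list[str]]]:
    """Validate variable names: spaces are an error, long names a warning.

    Returns (name, sanitized_name, warnings) per input.  Names are never
    silently truncated; a name over 10 characters earns a warning
    recommending a descriptive abbreviation.  Duplicates are an error.
    """
    seen = set()
    out = []
    for name in names:
        name = str(name)
        if any(ch.isspace() for ch in name):
            raise ValueError(
                f"space in variable name {name!r}: rename the column "
                "(e.g. Total_cholesterol) before analysis")
        if name in seen:
            raise ValueError(f"duplicate variable name {name!r}")
        seen.add(name)
        warns = []
        if len(name) > 10:
            warns.append(
                f"name {name!r} exceeds 10 characters; consider a "
                "descriptive abbreviation")
        out.append((name, name, warns))
    return out


# ---------------------------------------------------------------------------
# grid extraction


def _cell_empty(v) -> bool:
    return v is None or (isinstance(v, str) and v.strip() == "")


def _locate_region(grid: list[list]) -> tuple[int, int, int, int]:
    """Bounding box (r0, c0, r1, c1) of the single rectangular data block.

    An all-empty row or column strictly inside the bounding box means two
    disjoint blocks, which is ambiguous and therefore an error.
    """
    occupied = [(r, c) for r, row in enumerate(grid)
                for c, v in enumerate(row) if not _cell_empty(v)]
    if not occupied:
        raise ValueError("sheet contains no data")
    r0 = min(r for r, _ in occupied)
    r1 = max(r for r, _ in occupied)
    c0 = min(c for _, c in occupied)
    c1 = max(c for _, c in occupied)
    rows_used = {r for r, _ in occupied}
    cols_used = {c for _, c in occupied}
    for r in range(r0, r1 + 1):
        if r not in rows_used:
            raise ValueError(
                f"two disjoint data blocks: row {r + 1} is entirely empty "
                "inside the data region")
    for c in range(c0, c1 + 1):
        if c not in cols_used:
            raise ValueError(
                f"two disjoint data blocks: column {c + 1} is entirely "
                "empty inside the data region")
    return r0, c0, r1, c1


def _extract_table(grid: list[list], where: str) -> tuple[list[str], list[list]]:
    """Header row + data rows from the located region."""
    r0, c0, r1, c1 = _locate_region(grid)
    header = []
    for c in range(c0, c1 + 1):
        v = grid[r0][c] if c < len(grid[r0]) else None
        if _cell_empty(v):
            raise ValueError(
                f"{where}: header cell at row {r0 + 1}, column {c + 1} "
                "is empty — the region's first row must name every column")
        header.append(str(v).strip())
    rows = []
    for r in range(r0 + 1, r1 + 1):
        row = grid[r]
        rows.append([row[c] if c < len(row) else None for c in range(c0, c1 + 1)])
    if not rows:
        raise ValueError(f"{where}: no data rows below the header")
    return header, rows


def _read_grids(path: Path) -> list[tuple[str, list[list]]]:
    suffix = path.suffix.lower()
    if suffix == ".xlsx":
        import openpyxl

        wb = openpyxl.load_workbook(path, read_only=True, data_only=True)
        grids = []
        for ws in wb.worksheets:
            grids.append((ws.title, [list(row) for row in ws.iter_rows(values_only=True)]))
        wb.close()
        return grids
    if suffix == ".csv":
        with open(path, newline="", encoding="utf-8") as fh:
            grid = [list(row) for row in csv.reader(fh)]
        return [(path.stem, grid)]
    if suffix == ".xls":
        raise ValueError(
            "unsupported extension '.xls': re-save the workbook as .xlsx "
            "(or export to .csv)")
    raise ValueError(f"unsupported extension {suffix!r}: use .xlsx or .csv")


def _bundle_raw(name: str, header: list[str], rows: list[list],
                factor_name: str) -> DatasetBundle:
    if factor_name not in header:
        raise ValueError(
            f"factor column {factor_name!r} not found in sheet {name!r} "
            f"(names are case-sensitive); available columns: {header}")
    validate_names(header)
    fi = header.index(factor_name)
    response_names = [h for i, h in enumerate(header) if i != fi]
    if not response_names:
        raise ValueError(f"sheet {name!r} has no response columns")
    factor = [row[fi] for row in rows]
    raw_responses = {h: [row[i] for row in rows]
                     for i, h in enumerate(header) if i != fi}
    bundle = DatasetBundle(name=name, mode="raw", factor_name=factor_name,
                           factor=factor, raw_responses=raw_responses)
    for _, _, warns in validate_names(response_names):
        bundle.warnings.extend(warns)
    return bundle


def _bundle_summary(name: str, header: list[str], rows: list[list],
                    dispersion_kind: str, sizes_spec: str) -> DatasetBundle:
    if len(header) < 3 or (len(header) - 1) % 2 != 0:
        raise ValueError(
            f"sheet {name!r}: a summary sheet needs a group-label column "
            "followed by (mean, dispersion) column pairs; got "
            f"{len(header)} columns")
    if dispersion_kind not in ("sd", "sem"):
        raise ValueError("dispersion_kind must be 'sd' or 'sem'")
    labels = []
    for r, row in enumerate(rows):
        if is_missing(row[0]):
            raise ValueError(f"sheet {name!r}: empty group label at data row {r + 1}")
        labels.append(str(row[0]).strip())
    if sizes_spec is None:
        raise ValueError(
            "summary data need sample sizes: supply a common value "
            "(e.g. '15') or one per group (e.g. '15 14 15 16')")
    sizes = parse_sizes(sizes_spec, len(labels))
    response_names = [header[c] for c in range(1, len(header), 2)]
    validate_names(response_names)
    bundle = DatasetBundle(name=name, mode="summary", sizes=sizes)
    for _, _, warns in validate_names(response_names):
        bundle.warnings.extend(warns)
    for pos, c in enumerate(range(1, len(header), 2)):
        var = header[c]
        groups = []
        for r, row in enumerate(rows):
            mean_cell, disp_cell = row[c], row[c + 1]
            if is_missing(mean_cell) or is_missing(disp_cell):
                raise ValueError(
                    f"sheet {name!r}, variable {var!r}: missing mean or "
                    f"dispersion for group {labels[r]!r}")
            try:
                mean = float(mean_cell)
                disp = float(disp_cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"sheet {name!r}, variable {var!r}: non-numeric cell "
                    f"for group {labels[r]!r}") from None
            groups.append(GroupSummary(
                label=labels[r], n=sizes[r], mean=mean, dispersion=disp,
                dispersion_kind=dispersion_kind,
                display_precision=infer_precision(mean_cell)))
        bundle.summaries.append(ResponseSummary(variable=var, groups=tuple(groups)))
    return bundle


def read_workbook(path, scenario: str, factor_name: Optional[str] = None,
                  dispersion_kind: str = "sem",
                  sizes_spec: Optional[str] = None) -> Workbook:
    """Read an input file under one of the four scenarios.

    ``factor_name`` is required for the raw scenarios (S1/S2) and is
    case-sensitive.  ``sizes_spec`` is required for the summary scenarios
    (S3/S4); see :func:`parse_sizes`.  S1/S3 use the first sheet only;
    S2/S4 produce one dataset per sheet, in sheet order.
    """
    path = Path(path)
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    grids = _read_grids(path)
    if scenario not in MULTI_SHEET:
        grids = grids[:1]
    bundles = []
    for sheet_name, grid in grids:
        header, rows = _extract_table(grid, f"sheet {sheet_name!r}")
        if scenario in RAW_SCENARIOS:
            if factor_name is None:
                raise ValueError("raw scenarios need factor_name (case-sensitive)")
            bundles.append(_bundle_raw(sheet_name, header, rows, factor_name))
        else:
            bundles.append(_bundle_summary(sheet_name, header, rows,
                                           dispersion_kind, sizes_spec))
    return Workbook(path=str(path), scenario=scenario, sheets=bundles)
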