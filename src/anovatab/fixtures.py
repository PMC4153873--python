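"""Synthetic workbook generation and packaged reference summary data.

The generator realizes exactly the model one-way ANOVA assumes: each
response value is its group's true mean plus Normal(0, sigma) noise with a
common sigma.  Workbooks are written through openpyxl and then normalized
(fixed document timestamps, fixed zip entry order and dates) so the same
seed always yields byte-identical files.  Ground truth — true means, sigma,
and the exact sample moments of what was written — is stored in a flat
key=value sidecar next to the workbook for test consumption.

:func:`table1_data` packages a published 11-row reference table (plasma
metabolites and hormones of ZDF rats under three oral IFNT doses, means ±
SEM, n = 6 per group) together with its printed letter partitions, so the
whole pipeline can be regression-tested against a real table.
"""

from __future__ import annotations

import datetime
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .anova import GroupSummary, ResponseSummary

__all__ = [
    "FixtureConfig",
    "make_raw_workbook",
    "make_summary_workbook",
    "table1_data",
    "TABLE1_PARTITIONS",
]

_EPOCH = datetime.datetime(2014, 8, 27)
_ZIP_DATE = (2014, 8, 27, 0, 0, 0)


@dataclass(frozen=True)
class FixtureConfig:
    """Parameters of the synthetic one-way layout.

    Defaults emulate a small toy workbook: one factor ("group") with four
    levels A-D and six response variables V1-V6, n = 10 per group, common
    within-group SD sigma = 1, and true group means spread over one sigma
    (a moderate, realistic effect).  ``scenario`` S2/S4 write ``n_sheets``
    datasets, one per sheet.
    """

    seed: int = 0
    levels: tuple[str, ...] = ("A", "B", "C", "D")
    n: tuple[int, ...] = (10, 10, 10, 10)
    group_effects: tuple[float, ...] = (0.0, 0.35, 0.7, 1.05)
    sigma: float = 1.0
    n_responses: int = 6
    scenario: str = "S1"
    n_sheets: int = 3
    factor_name: str = "group"

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if len(self.levels) < 2:
            raise ValueError("need at least 2 factor levels")
        if len(self.n) != len(self.levels) or any(v < 2 for v in self.n):
            raise ValueError("need one sample size >= 2 per level")
        if len(self.group_effects) != len(self.levels):
            raise ValueError("need one group effect per level")
        if self.n_responses < 1:
            raise ValueError("need at least one response variable")
        if self.scenario not in ("S1", "S2", "S3", "S4"):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def _normalize_zip(path: Path) -> None:
    """Rewrite a zip with sorted entries and fixed dates (determinism)."""
    with zipfile.ZipFile(path) as zf:
        entries = {name: zf.read(name) for name in zf.namelist()}
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        for name in sorted(entries):
            info = zipfile.ZipInfo(name, date_time=_ZIP_DATE)
            info.compress_type = zipfile.ZIP_DEFLATED
            info.external_attr = 0o600 << 16
            zf.writestr(info, entries[name])


def _new_workbook():
    import openpyxl

    wb = openpyxl.Workbook()
    wb.properties.created = _EPOCH
    wb.properties.modified = _EPOCH
    wb.properties.creator = "anovatab"
    wb.properties.lastModifiedBy = "anovatab"
    return wb


def _write_truth(path: Path, records: dict) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for key in sorted(records):
            fh.write(f"{key}={records[key]!r}\n")


def _draw_dataset(rng, config: FixtureConfig):
    """Per-response raw columns plus exact sample moments."""
    factor, columns, truth = [], {}, {}
    for level, n in zip(config.levels, config.n):
        factor.extend([level] * n)
    for v in range(1, config.n_responses + 1):
        name = f"V{v}"
        col = []
        for level, n, eff in zip(config.levels, config.n, config.group_effects):
            ys = eff + config.sigma * rng.standard_normal(n)
            col.extend(float(y) for y in ys)
            truth[f"{name}.{level}.true_mean"] = eff
            truth[f"{name}.{level}.n"] = n
            truth[f"{name}.{level}.sample_mean"] = float(np.mean(ys))
            truth[f"{name}.{level}.sample_sd"] = float(np.std(ys, ddof=1))
        columns[name] = col
        truth[f"{name}.sigma"] = config.sigma
    return factor, columns, truth


def make_raw_workbook(config: FixtureConfig, path) -> dict:
    """Write a raw-data workbook (S1: one sheet; S2: one dataset per sheet).

    Returns the ground-truth record, which is also written to a
    ``<path>.truth.txt`` sidecar.  Identical configs (same seed) yield
    byte-identical workbooks.
    """
    if config.scenario not in ("S1", "S2"):
        raise ValueError("make_raw_workbook handles scenarios S1 and S2")
    path = Path(path)
    rng = np.random.default_rng(config.seed)
    wb = _new_workbook()
    truth: dict = {}
    n_sheets = config.n_sheets if config.scenario == "S2" else 1
    for s in range(n_sheets):
        ws = wb.active if s == 0 else wb.create_sheet()
        ws.title = f"Sheet{s + 1}"
        factor, columns, sheet_truth = _draw_dataset(rng, config)
        ws.append([config.factor_name] + list(columns))
        for r in range(len(factor)):
            ws.append([factor[r]] + [columns[name][r] for name in columns])
        for key, val in sheet_truth.items():
            truth[f"{ws.title}.{key}"] = val
    wb.save(path)
    _normalize_zip(path)
    _write_truth(path.with_name(path.name + ".truth.txt"), truth)
    return truth


def make_summary_workbook(config: FixtureConfig, path,
                          dispersion_kind: str = "sem",
                          levels: Optional[Sequence[str]] = None,
                          n_responses: int = 2) -> dict:
    """Write a summary-data workbook (S3: one sheet; S4: one per sheet).

    Layout: first column = group label, then a (mean, dispersion) column
    pair per response, headers ``Var1``, ``Var2``, ...; the dispersion
    header names the kind (``SD``/``SEM``).  Defaults give two responses
    over four levels L1-L4.  Summaries are the exact sample moments of a
    draw from the generator's normal model.
    """
    if config.scenario not in ("S3", "S4"):
        raise ValueError("make_summary_workbook handles scenarios S3 and S4")
    if dispersion_kind not in ("sd", "sem"):
        raise ValueError("dispersion_kind must be 'sd' or 'sem'")
    path = Path(path)
    labels = list(levels) if levels is not None else [f"L{i + 1}" for i in range(len(config.levels))]
    if len(labels) != len(config.levels):
        raise ValueError("levels must match config group count")
    rng = np.random.default_rng(config.seed)
    wb = _new_workbook()
    truth: dict = {}
    n_sheets = config.n_sheets if config.scenario == "S4" else 1
    disp_header = dispersion_kind.upper()
    for s in range(n_sheets):
        ws = wb.active if s == 0 else wb.create_sheet()
        ws.title = f"Sheet{s + 1}"
        header = ["Group"]
        names = [f"Var{v + 1}" for v in range(n_responses)]
        for name in names:
            header.extend([name, disp_header])
        ws.append(header)
        per_group_rows = {lab: [lab] for lab in labels}
        for name in names:
            for lab, n, eff in zip(labels, config.n, config.group_effects):
                ys = eff + config.sigma * rng.standard_normal(n)
                mean = float(np.mean(ys))
                sd = float(np.std(ys, ddof=1))
                disp = sd if dispersion_kind == "sd" else sd / np.sqrt(n)
                per_group_rows[lab].extend([mean, float(disp)])
                truth[f"{ws.title}.{name}.{lab}.true_mean"] = eff
                truth[f"{ws.title}.{name}.{lab}.n"] = n
                truth[f"{ws.title}.{name}.{lab}.sample_mean"] = mean
                truth[f"{ws.title}.{name}.{lab}.sample_sd"] = sd
        for lab in labels:
            ws.append(per_group_rows[lab])
    wb.save(path)
    _normalize_zip(path)
    _write_truth(path.with_name(path.name + ".truth.txt"), truth)
    return truth


# ---------------------------------------------------------------------------
# packaged reference table: plasma metabolites/hormones of ZDF rats under
# oral IFNT doses 0/4/8 ug/kg BW/day, means +/- SEM, n = 6 per group

_TABLE1_ROWS = [
    # (variable, (means as printed), (SEMs as printed), lettered?)
    ("Arginine",          ("110", "115", "149"),    ("4", "5", "6"),       True),
    ("Valine",            ("219", "201", "172"),    ("9", "7", "6"),       True),
    ("Isoleucine",        ("208", "206", "178"),    ("8", "7", "6"),       True),
    ("Leucine",           ("245", "233", "196"),    ("10", "9", "8"),      True),
    ("Glucose",           ("24.5", "23.8", "21.9"), ("0.3", "0.4", "0.4"), True),
    ("FFA",               ("1.60", "1.53", "1.34"), ("0.06", "0.05", "0.05"), True),
    ("Triacylglycerol",   ("6.05", "5.90", "5.17"), ("0.13", "0.27", "0.11"), True),
    ("Cholesterol",       ("5.18", "4.94", "4.23"), ("0.23", "0.24", "0.13"), True),
    ("Insulin",           ("307", "294", "301"),    ("10", "11", "7"),     False),
    ("Adiponectin",       ("2.78", "2.94", "2.64"), ("0.08", "0.09", "0.13"), False),
    ("Leptin",            ("19.6", "19.3", "13.7"), ("1.2", "1.0", "0.9"), True),
]

_TABLE1_LABELS = ("0", "4", "8")
_TABLE1_N = 6

#: Printed letter partitions: the lettered rows separate the highest dose
#: from the two lower doses; insulin and adiponectin carry no letters.
TABLE1_PARTITIONS: dict[str, frozenset] = {
    var: (frozenset({frozenset({"0", "4"}), frozenset({"8"})}) if lettered
          else frozenset({frozenset({"0", "4", "8"})}))
    for var, _, _, lettered in _TABLE1_ROWS
}


def _decimals(text: str) -> int:
    return len(text.split(".", 1)[1]) if "." in text else 0


def table1_data() -> list[ResponseSummary]:
    """The packaged 11-response reference table as summary data.

    Three dose groups labelled "0", "4", "8" (ug IFNT/kg BW/day), n = 6
    each, dispersion given as SEM, display precision taken from the
    printed values.  Printed letter partitions are in
    :data:`TABLE1_PARTITIONS`.
    """
    out = []
    for var, means, sems, _ in _TABLE1_ROWS:
        groups = tuple(
            GroupSummary(label=lab, n=_TABLE1_N, mean=float(m),
                         dispersion=float(s), dispersion_kind="sem",
                         display_precision=_decimals(m))
            for lab, m, s in zip(_TABLE1_LABELS, means, sems))
        out.append(ResponseSummary(variable=var, groups=groups))
    return out
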