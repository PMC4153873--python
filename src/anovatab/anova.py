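"""One-way ANOVA from group summary statistics.

Raw data are first reduced to per-group summaries (n, mean, SD), so the
raw-data and summary-data input paths share a single computation.  The
model is the usual fixed-effects one-way layout: k groups, normal errors
with a common variance, differing only in their means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

from scipy import stats

__all__ = [
    "GroupSummary",
    "ResponseSummary",
    "AnovaResult",
    "summarize_raw",
    "anova_from_summary",
    "anova_from_raw",
    "is_missing",
    "harmonic_mean_n",
]

#: Tokens treated as missing in CSV/text input, besides empty cells.
NA_TOKENS = {"", "na", "n/a", "nan", "null", "none", "."}


def is_missing(value) -> bool:
    """True for empty cells and the conventional NA markers."""
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    if isinstance(value, str) and value.strip().lower() in NA_TOKENS:
        return True
    return False


@dataclass(frozen=True)
class GroupSummary:
    """Summary statistics for one treatment group.

    ``dispersion`` is either a sample SD or a SEM, declared by
    ``dispersion_kind``; the SD is recovered as ``SEM * sqrt(n)`` when the
    input is a SEM.  ``display_precision`` records the number of decimal
    places the source printed the mean with, so rendered tables can echo
    the input precision.
    """

    label: str
    n: int
    mean: float
    dispersion: float
    dispersion_kind: str = "sd"  # "sd" | "sem"
    display_precision: int = 2

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"group {self.label!r} too small (n={self.n} < 2)")
        if self.dispersion < 0:
            raise ValueError(f"group {self.label!r}: dispersion must be >= 0")
        if self.dispersion_kind not in ("sd", "sem"):
            raise ValueError(f"dispersion_kind must be 'sd' or 'sem', got {self.dispersion_kind!r}")
        if self.display_precision < 0:
            raise ValueError("display_precision must be >= 0")

    @property
    def sd(self) -> float:
        """Sample standard deviation (SEM converted via s = SEM * sqrt(n))."""
        if self.dispersion_kind == "sd":
            return self.dispersion
        return self.dispersion * math.sqrt(self.n)

    @property
    def sem(self) -> float:
        """Standard error of the group mean, SD / sqrt(n)."""
        if self.dispersion_kind == "sem":
            return self.dispersion
        return self.dispersion / math.sqrt(self.n)


@dataclass(frozen=True)
class ResponseSummary:
    """One response variable summarized per group, in source order."""

    variable: str
    groups: tuple[GroupSummary, ...]

    def __post_init__(self):
        object.__setattr__(self, "groups", tuple(self.groups))
        if len(self.groups) < 2:
            raise ValueError("factor must have >=2 levels")
        labels = [g.label for g in self.groups]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate group labels in {self.variable!r}: {labels}")
        kinds = {g.dispersion_kind for g in self.groups}
        if len(kinds) != 1:
            raise ValueError("all groups must share one dispersion kind")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(g.label for g in self.groups)

    @property
    def k(self) -> int:
        return len(self.groups)


@dataclass(frozen=True)
class AnovaResult:
    """Omnibus F-test decomposition for a one-way layout.

    ``mse`` is the pooled within-group variance (= ``ms_within``), the
    denominator of F and of every pairwise standard error downstream.
    ``pooled_sem`` is sqrt(MSE / n_h) with n_h the common group size in a
    balanced design, or the harmonic mean of the n_i otherwise.
    """

    k: int
    N: int
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ms_between: float
    ms_within: float
    f_stat: float
    p_value: float
    pooled_sem: float

    @property
    def mse(self) -> float:
        return self.ms_within


def harmonic_mean_n(sizes: Sequence[int]) -> float:
    """Harmonic mean of group sizes; equals the common n when balanced."""
    return len(sizes) / sum(1.0 / n for n in sizes)


def summarize_raw(factor_values: Sequence, response_values: Sequence,
                  variable: str = "response",
                  display_precision: int = 2) -> ResponseSummary:
    """Reduce raw observations to per-group (n, mean, sample SD).

    Rows where either the factor or the response is missing are dropped.
    Groups appear in first-appearance order.  The sample SD uses the n-1
    denominator.
    """
    if len(factor_values) != len(response_values):
        raise ValueError("factor and response columns have different lengths")
    per_group: dict[str, list[float]] = {}
    for row, (f, y) in enumerate(zip(factor_values, response_values)):
        if is_missing(f) or is_missing(y):
            continue
        try:
            yv = float(y)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric response value {y!r} at row {row} of {variable!r}"
            ) from None
        per_group.setdefault(str(f), []).append(yv)
    if len(per_group) < 2:
        raise ValueError("factor must have >=2 levels")
    groups = []
    for label, ys in per_group.items():
        n = len(ys)
        if n < 2:
            raise ValueError(f"group too small: {label!r} has n={n} < 2")
        mean = sum(ys) / n
        sd = math.sqrt(sum((v - mean) ** 2 for v in ys) / (n - 1))
        groups.append(GroupSummary(label=label, n=n, mean=mean, dispersion=sd,
                                   dispersion_kind="sd",
                                   display_precision=display_precision))
    return ResponseSummary(variable=variable, groups=tuple(groups))


def anova_from_summary(summary: ResponseSummary) -> AnovaResult:
    """One-way ANOVA computed from group sizes, means and SDs/SEMs.

    Decomposition: SSB = sum n_i (m_i - grand)^2 over groups with
    grand = sum n_i m_i / N, and SSW = sum (n_i - 1) s_i^2; F = MSB/MSW
    with p the upper tail of F(k-1, N-k).
    """
    groups = summary.groups
    k = len(groups)
    ns = [g.n for g in groups]
    means = [g.mean for g in groups]
    sds = [g.sd for g in groups]
    N = sum(ns)
    df_b, df_w = k - 1, N - k
    grand = sum(n * m for n, m in zip(ns, means)) / N
    ss_b = sum(n * (m - grand) ** 2 for n, m in zip(ns, means))
    ss_w = sum((n - 1) * s * s for n, s in zip(ns, sds))
    ms_b = ss_b / df_b
    ms_w = ss_w / df_w
    if ms_w == 0.0:
        if ss_b == 0.0:
            warnings.warn(
                "all group SDs are zero and all means equal: "
                "F is undefined; reporting p = 1", RuntimeWarning)
            f_stat, p = math.nan, 1.0
        else:
            raise ValueError("zero within-group variance")
    else:
        f_stat = ms_b / ms_w
        p = float(stats.f.sf(f_stat, df_b, df_w))
    n_h = harmonic_mean_n(ns)
    pooled_sem = math.sqrt(ms_w / n_h)
    return AnovaResult(k=k, N=N, df_between=df_b, df_within=df_w,
                       ss_between=ss_b, ss_within=ss_w,
                       ms_between=ms_b, ms_within=ms_w,
                       f_stat=f_stat, p_value=p, pooled_sem=pooled_sem)


def anova_from_raw(factor_values: Sequence, response_values: Sequence,
                   variable: str = "response") -> AnovaResult:
    """ANOVA on raw columns: summarize first, then the summary path."""
    return anova_from_summary(summarize_raw(factor_values, response_values,
                                            variable=variable))
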