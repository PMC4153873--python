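"""All-pairwise multiple comparison procedures.

Four tests are provided, ordered from most to least conservative on the
decision level: Tukey-Kramer (single-step studentized range), the
Student-Newman-Keuls (SNK) stepwise range test, Duncan's multiple range
test (SNK with relaxed per-span protection levels), and Fisher's LSD
(pairwise t-tests on the pooled MSE, optionally Bonferroni/Holm adjusted).

Every test returns an :class:`MCPResult` holding all k(k-1)/2 pairwise
comparisons plus the symmetric boolean significance relation consumed by
the compact-letter-display builder.

For the stepwise tests (SNK, Duncan) the normative output is the decision
and the critical range used; the attached per-pair p-value is informational
only — it is the span-r studentized-range tail probability and is not
calibrated to control the family-wise error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .anova import AnovaResult, ResponseSummary, anova_from_summary, harmonic_mean_n

__all__ = [
    "PairwiseComparison",
    "MCPResult",
    "adjust_pvalues",
    "lsd_test",
    "tukey_kramer",
    "snk_test",
    "duncan_test",
    "run_posthoc",
    "TEST_NAMES",
]

TEST_NAMES = {"lsd": "LSD", "tukey": "Tukey-Kramer", "snk": "SNK", "duncan": "Duncan"}


@dataclass(frozen=True)
class PairwiseComparison:
    """One pairwise mean comparison.

    ``span`` is the number of ordered means the pair spans inclusive; it is
    always 2 except for the range tests.  ``p_adjusted`` is None for the
    stepwise tests, which do not define a single FWER-adjusted p.
    """

    pair: tuple[str, str]
    estimate: float
    std_error: float
    statistic: float
    span: int
    p_raw: Optional[float]
    p_adjusted: Optional[float]
    significant: bool
    critical_range: Optional[float] = None


@dataclass(frozen=True)
class MCPResult:
    """All pairwise comparisons for one response plus the significance relation.

    ``relation`` is a symmetric boolean matrix over ``labels`` (input group
    order) with a false diagonal; ``relation[i, j]`` is True when groups i
    and j differ significantly at ``alpha``.
    """

    method: str
    adjust: str
    alpha: float
    labels: tuple[str, ...]
    comparisons: tuple[PairwiseComparison, ...]
    relation: np.ndarray

    def __post_init__(self):
        r = np.asarray(self.relation, dtype=bool)
        if r.shape != (len(self.labels), len(self.labels)):
            raise ValueError("relation shape does not match labels")
        if not np.array_equal(r, r.T) or r.diagonal().any():
            raise ValueError("relation must be symmetric with a false diagonal")
        object.__setattr__(self, "relation", r)


def adjust_pvalues(pvals: Sequence[float], method: str) -> list[float]:
    """Bonferroni or Holm step-down adjustment of a p-value family.

    Bonferroni: min(1, m*p).  Holm: sort ascending, multiply the i-th
    (1-based) by (m - i + 1), enforce a running maximum, cap at 1, and
    restore the input order.
    """
    p = list(map(float, pvals))
    if any(not (0.0 <= v <= 1.0) for v in p):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if method == "bonferroni":
        return [min(1.0, m * v) for v in p]
    if method == "holm":
        order = sorted(range(m), key=lambda i: p[i])
        out = [0.0] * m
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            out[i] = min(1.0, running)
        return out
    raise ValueError(f"unknown adjustment method {method!r}")


def _check_inputs(summary: ResponseSummary, anova: AnovaResult, alpha: float):
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if anova.df_within < 1:
        raise ValueError("within-group degrees of freedom must be >= 1")
    if anova.mse <= 0.0:
        raise ValueError("zero within-group variance")
    if anova.k != summary.k or anova.N != sum(g.n for g in summary.groups):
        raise ValueError("ANOVA result does not match the summary it is paired with")


def _relation_from(labels, comparisons):
    idx = {lab: i for i, lab in enumerate(labels)}
    rel = np.zeros((len(labels), len(labels)), dtype=bool)
    for c in comparisons:
        i, j = idx[c.pair[0]], idx[c.pair[1]]
        rel[i, j] = rel[j, i] = c.significant
    return rel


def lsd_test(summary: ResponseSummary, anova: AnovaResult = None,
             alpha: float = 0.05, adjust: str = "none") -> MCPResult:
    """Fisher's least significant difference test.

    Per pair: t = (m_i - m_j) / sqrt(MSE (1/n_i + 1/n_j)) referred to
    t(df_within), two-sided.  With ``adjust`` in {bonferroni, holm} the
    family of raw p-values is adjusted before the alpha decision.
    """
    if anova is None:
        anova = anova_from_summary(summary)
    _check_inputs(summary, anova, alpha)
    if adjust not in ("none", "bonferroni", "holm"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    g = summary.groups
    pairs, p_raws, rows = [], [], []
    for i in range(len(g)):
        for j in range(i + 1, len(g)):
            est = g[i].mean - g[j].mean
            se = math.sqrt(anova.mse * (1.0 / g[i].n + 1.0 / g[j].n))
            t = est / se
            p = float(2.0 * stats.t.sf(abs(t), anova.df_within))
            pairs.append((g[i].label, g[j].label))
            p_raws.append(p)
            rows.append((est, se, t))
    p_adj = list(p_raws) if adjust == "none" else adjust_pvalues(p_raws, adjust)
    comparisons = tuple(
        PairwiseComparison(pair=pr, estimate=est, std_error=se, statistic=t,
                           span=2, p_raw=praw, p_adjusted=padj,
                           significant=padj <= alpha)
        for pr, praw, padj, (est, se, t) in zip(pairs, p_raws, p_adj, rows))
    return MCPResult(method="LSD", adjust=adjust, alpha=alpha,
                     labels=summary.labels, comparisons=comparisons,
                     relation=_relation_from(summary.labels, comparisons))


def tukey_kramer(summary: ResponseSummary, anova: AnovaResult = None,
                 alpha: float = 0.05) -> MCPResult:
    """Tukey's HSD with the Kramer pairwise standard error for unbalanced n.

    Per pair: q = |m_i - m_j| / sqrt((MSE/2)(1/n_i + 1/n_j)); the adjusted
    p is the upper tail of the studentized range distribution with
    parameters (k, df_within) at q.
    """
    if anova is None:
        anova = anova_from_summary(summary)
    _check_inputs(summary, anova, alpha)
    g = summary.groups
    comparisons = []
    for i in range(len(g)):
        for j in range(i + 1, len(g)):
            est = g[i].mean - g[j].mean
            se = math.sqrt((anova.mse / 2.0) * (1.0 / g[i].n + 1.0 / g[j].n))
            q = abs(est) / se
            p = float(stats.studentized_range.sf(q, anova.k, anova.df_within))
            p = min(1.0, max(0.0, p))
            comparisons.append(PairwiseComparison(
                pair=(g[i].label, g[j].label), estimate=est, std_error=se,
                statistic=q, span=2, p_raw=p, p_adjusted=p,
                significant=p <= alpha))
    comparisons = tuple(comparisons)
    return MCPResult(method="TK", adjust="none", alpha=alpha,
                     labels=summary.labels, comparisons=comparisons,
                     relation=_relation_from(summary.labels, comparisons))


@lru_cache(maxsize=4096)
def _q_crit(alpha: float, r: int, df: int) -> float:
    return float(stats.studentized_range.ppf(1.0 - alpha, r, df))


def _range_test(summary: ResponseSummary, anova: AnovaResult, alpha: float,
                method: str) -> MCPResult:
    """Shared SNK/Duncan machinery.

    Means are ordered descending (ties broken by input order).  For a pair
    whose endpoints span r ordered means, the critical range is
    q_{alpha_r}(r, df_within) * sqrt(MSE / n_h) with n_h the harmonic mean
    of the spanned group sizes.  SNK uses alpha_r = alpha; Duncan uses the
    protection level alpha_r = 1 - (1 - alpha)^(r-1).  Spans are examined
    widest-first: when a span's extreme difference fails its critical
    range, every pair inside the span is declared not significant without
    testing (blocking).
    """
    if anova is None:
        anova = anova_from_summary(summary)
    _check_inputs(summary, anova, alpha)
    g = summary.groups
    k = len(g)
    order = sorted(range(k), key=lambda i: -g[i].mean)  # stable: ties by input order
    blocked: list[tuple[int, int]] = []
    comparisons = []
    for r in range(k, 1, -1):
        alpha_r = alpha if method == "SNK" else 1.0 - (1.0 - alpha) ** (r - 1)
        for a in range(0, k - r + 1):
            b = a + r - 1
            gi, gj = g[order[a]], g[order[b]]
            spanned = [g[order[t]].n for t in range(a, b + 1)]
            n_h = harmonic_mean_n(spanned)
            se = math.sqrt(anova.mse / n_h)
            crit = _q_crit(alpha_r, r, anova.df_within) * se
            diff = gi.mean - gj.mean  # >= 0 by the ordering
            q = diff / se
            p_info = float(stats.studentized_range.sf(q, r, anova.df_within))
            is_blocked = any(a2 <= a and b <= b2 for a2, b2 in blocked)
            if is_blocked:
                sig = False
            else:
                sig = diff > crit
                if not sig:
                    blocked.append((a, b))
            comparisons.append(PairwiseComparison(
                pair=(gi.label, gj.label), estimate=gi.mean - gj.mean,
                std_error=se, statistic=q, span=r, p_raw=p_info,
                p_adjusted=None, significant=sig, critical_range=crit))
    comparisons = tuple(comparisons)
    return MCPResult(method=method, adjust="none", alpha=alpha,
                     labels=summary.labels, comparisons=comparisons,
                     relation=_relation_from(summary.labels, comparisons))


def snk_test(summary: ResponseSummary, anova: AnovaResult = None,
             alpha: float = 0.05) -> MCPResult:
    """Student-Newman-Keuls stepwise range test."""
    return _range_test(summary, anova, alpha, "SNK")


def duncan_test(summary: ResponseSummary, anova: AnovaResult = None,
                alpha: float = 0.05) -> MCPResult:
    """Duncan's multiple range test (SNK with relaxed protection levels)."""
    return _range_test(summary, anova, alpha, "DC")


def run_posthoc(summary: ResponseSummary, anova: AnovaResult, test: str,
                alpha: float = 0.05, adjust: str = "none",
                protected: bool = False) -> MCPResult:
    """Dispatch to a test by name ('lsd', 'tukey', 'snk', 'duncan').

    With ``protected=True`` the classical two-step procedure is enforced:
    when the omnibus p exceeds alpha, all pairs are reported not
    significant without running the pairwise test.
    """
    if test not in TEST_NAMES:
        raise ValueError(f"unknown test {test!r}; choose from {sorted(TEST_NAMES)}")
    if adjust != "none" and test != "lsd":
        raise ValueError("p-value adjustment applies to the LSD test only")
    if protected and anova.p_value > alpha:
        k = summary.k
        return MCPResult(method=TEST_NAMES[test], adjust=adjust, alpha=alpha,
                         labels=summary.labels, comparisons=(),
                         relation=np.zeros((k, k), dtype=bool))
    if test == "lsd":
        return lsd_test(summary, anova, alpha, adjust)
    if test == "tukey":
        return tukey_kramer(summary, anova, alpha)
    if test == "snk":
        return snk_test(summary, anova, alpha)
    return duncan_test(summary, anova, alpha)
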