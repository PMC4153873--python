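"""End-to-end convenience layer: dataset bundle -> analysis -> TableSpec."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .anova import AnovaResult, ResponseSummary, anova_from_summary
from .cld import LetterDisplay, insert_absorb
from .posthoc import MCPResult, TEST_NAMES, run_posthoc
from .render import TableSpec, build_table
from .table_io import DatasetBundle

__all__ = ["ResponseResult", "analyze_response", "analyze_bundle"]


@dataclass(frozen=True)
class ResponseResult:
    """Everything computed for one response variable."""

    summary: ResponseSummary
    anova: AnovaResult
    mcp: MCPResult
    letters: LetterDisplay


def analyze_response(summary: ResponseSummary, test: str = "snk",
                     alpha: float = 0.05, adjust: str = "none",
                     protected: bool = False) -> ResponseResult:
    """Omnibus ANOVA, post-hoc test and letter display for one response.

    Letters are ranked so 'a' attaches to the class containing the largest
    mean (a presentation convention only; the partition is the contract).
    """
    anova = anova_from_summary(summary)
    mcp = run_posthoc(summary, anova, test=test, alpha=alpha, adjust=adjust,
                      protected=protected)
    means = [g.mean for g in summary.groups]
    desc_rank = [sorted(means, reverse=True).index(m) for m in means]
    letters = insert_absorb(summary.labels, mcp.relation, ranks=desc_rank)
    return ResponseResult(summary=summary, anova=anova, mcp=mcp, letters=letters)


def analyze_bundle(bundle: DatasetBundle, test: str = "snk",
                   alpha: float = 0.05, adjust: str = "none",
                   protected: bool = False, mode: str = "per_group_sem",
                   precision: Optional[int] = None,
                   title: str = "") -> tuple[list[ResponseResult], TableSpec]:
    """Analyze every response of a bundle and build its table."""
    results = [analyze_response(s, test=test, alpha=alpha, adjust=adjust,
                                protected=protected)
               for s in bundle.response_summaries()]
    table = build_table([(r.summary, r.anova, r.mcp, r.letters) for r in results],
                        mode=mode, alpha=alpha, test_name=TEST_NAMES[test],
                        title=title or bundle.name, precision=precision)
    return results, table
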