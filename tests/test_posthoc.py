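"""Unit tests for the multiple comparison procedures."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from anovatab import (
    GroupSummary,
    ResponseSummary,
    adjust_pvalues,
    anova_from_summary,
    duncan_test,
    lsd_test,
    run_posthoc,
    snk_test,
    tukey_kramer,
)
from conftest import random_summary


def make_summary(ns, means, disps, kind="sd"):
    return ResponseSummary(variable="y", groups=tuple(
        GroupSummary(label=f"g{i}", n=n, mean=m, dispersion=d, dispersion_kind=kind)
        for i, (n, m, d) in enumerate(zip(ns, means, disps))))


CHOLESTEROL = make_summary([6, 6, 6], [5.18, 4.94, 4.23],
                           [0.23, 0.24, 0.13], kind="sem")
ADIPONECTIN = make_summary([6, 6, 6], [2.78, 2.94, 2.64],
                           [0.08, 0.09, 0.13], kind="sem")
ARGININE = make_summary([6, 6, 6], [110, 115, 149], [4, 5, 6], kind="sem")


def sig_pairs(mcp):
    return {frozenset(c.pair) for c in mcp.comparisons if c.significant}


class TestAdjustPvalues:
    @pytest.mark.parametrize("pvals,method,expected", [
        ([0.01, 0.04, 0.03], "bonferroni", [0.03, 0.12, 0.09]),
        ([0.01, 0.04, 0.03], "holm", [0.03, 0.06, 0.06]),
        ([0.5, 0.6], "bonferroni", [1.0, 1.0]),
    ])
    def test_examples(self, pvals, method, expected):
        assert adjust_pvalues(pvals, method) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [0.2, float("nan")]])
    def test_rejects_out_of_range(self, bad):
        with pytest.raises(ValueError):
            adjust_pvalues(bad, "bonferroni")

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    def test_against_reference_implementation(self, pvals):
        from statsmodels.stats.multitest import multipletests

        for method in ("bonferroni", "holm"):
            mine = adjust_pvalues(pvals, method)
            ref = multipletests(pvals, alpha=0.05, method=method)[1]
            assert mine == pytest.approx(list(ref), abs=1e-12)
            holm = adjust_pvalues(pvals, "holm")
            bonf = adjust_pvalues(pvals, "bonferroni")
            for h, b, raw in zip(holm, bonf, pvals):
                assert raw <= h <= b <= 1.0


class TestLsd:
    def test_cholesterol_pair(self):
        # MSE reconstructed from the printed SEMs is 0.2548; the pair
        # (4.94, 4.23) gives t = 0.71/sqrt(MSE/3) ~ 2.44, p ~ 0.028
        res = lsd_test(CHOLESTEROL, alpha=0.05)
        pair = next(c for c in res.comparisons if c.pair == ("g1", "g2"))
        assert pair.statistic == pytest.approx(2.44, abs=0.01)
        assert pair.p_raw == pytest.approx(0.028, abs=0.002)
        assert pair.significant

    def test_identical_means(self):
        res = lsd_test(make_summary([5, 5], [2.0, 2.0], [1, 1]))
        (c,) = res.comparisons
        assert c.statistic == 0.0
        assert c.p_raw == 1.0
        assert not c.significant

    def test_bonferroni_is_definitional(self):
        res = lsd_test(CHOLESTEROL, adjust="bonferroni")
        for c in res.comparisons:
            assert c.p_adjusted == pytest.approx(min(1.0, 3 * c.p_raw), rel=1e-12)

    def test_zero_mse_rejected(self):
        import dataclasses

        summary = make_summary([3, 3], [1.0, 2.0], [1, 1])
        anova = dataclasses.replace(anova_from_summary(summary), ms_within=0.0)
        with pytest.raises(ValueError, match="zero within-group variance"):
            lsd_test(summary, anova)


class TestTukeyKramer:
    def test_arginine_decisions(self):
        res = tukey_kramer(ARGININE)
        assert sig_pairs(res) == {frozenset({"g0", "g2"}), frozenset({"g1", "g2"})}

    def test_k2_equals_lsd_p(self, rng):
        for _ in range(20):
            s = random_summary(rng, k=2, balanced=False)
            p_tk = tukey_kramer(s).comparisons[0].p_adjusted
            p_lsd = lsd_test(s).comparisons[0].p_raw
            assert p_tk == pytest.approx(p_lsd, abs=1e-8)

    def test_equal_means_never_significant(self):
        res = tukey_kramer(make_summary([4, 4, 4], [1, 1, 1], [1, 1, 1]))
        assert not sig_pairs(res)

    def test_p_at_least_lsd_raw(self, rng):
        for _ in range(20):
            s = random_summary(rng)
            tk = {c.pair: c.p_adjusted for c in tukey_kramer(s).comparisons}
            raw = {c.pair: c.p_raw for c in lsd_test(s).comparisons}
            for pair in tk:
                assert tk[pair] >= raw[pair] - 1e-12

    def test_against_statsmodels(self, rng):
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        for _ in range(5):
            k = int(rng.integers(3, 5))
            n = int(rng.choice([5, 8]))
            data = [rng.normal(rng.uniform(-1, 1), 1, n) for _ in range(k)]
            factor = sum(([f"g{i}"] * n for i in range(k)), [])
            y = np.concatenate(data)
            from anovatab import summarize_raw
            s = summarize_raw(factor, y)
            mine = {c.pair: c.p_adjusted for c in tukey_kramer(s).comparisons}
            ref = pairwise_tukeyhsd(y, factor, alpha=0.05)
            for row, p in zip(ref.summary().data[1:], ref.pvalues):
                key = (str(row[0]), str(row[1]))
                got = mine.get(key) or mine.get((key[1], key[0]))
                assert got == pytest.approx(float(p), abs=1e-6)


class TestRangeTests:
    def test_snk_cholesterol(self):
        res = snk_test(CHOLESTEROL)
        assert sig_pairs(res) == {frozenset({"g0", "g2"}), frozenset({"g1", "g2"})}
        spans = {c.pair: c.span for c in res.comparisons}
        assert spans[("g0", "g2")] == 3
        assert spans[("g0", "g1")] == 2

    def test_snk_blocking_adiponectin(self):
        # widest span's q ~ 2.93 < q(0.05; 3, 15) ~ 3.67: everything blocked
        res = snk_test(ADIPONECTIN)
        assert not sig_pairs(res)
        widest = next(c for c in res.comparisons if c.span == 3)
        assert widest.statistic == pytest.approx(2.93, abs=0.01)

    def test_k2_snk_equals_lsd_decision(self, rng):
        for _ in range(20):
            s = random_summary(rng, k=2)
            assert (sig_pairs(snk_test(s)) ==
                    sig_pairs(lsd_test(s, adjust="none")))

    def test_duncan_protection_level_at_span2(self, rng):
        # alpha_r = alpha at r = 2, so Duncan and SNK agree on adjacent pairs
        # unless blocking from wider spans differs
        s = random_summary(rng, k=3)
        snk = {c.pair: c.critical_range for c in snk_test(s).comparisons}
        dc = {c.pair: c.critical_range for c in duncan_test(s).comparisons}
        for pair in snk:
            assert dc[pair] <= snk[pair] + 1e-12  # alpha_r >= alpha

    def test_duncan_rejects_whatever_snk_rejects(self, rng):
        for _ in range(30):
            s = random_summary(rng, balanced=True)
            assert sig_pairs(snk_test(s)) <= sig_pairs(duncan_test(s))

    def test_power_ordering_chain(self, rng):
        # decision-level power ordering: TK <= SNK <= Duncan <= raw LSD
        for _ in range(30):
            s = random_summary(rng, balanced=True)
            tk, snk = sig_pairs(tukey_kramer(s)), sig_pairs(snk_test(s))
            dc, lsd = sig_pairs(duncan_test(s)), sig_pairs(lsd_test(s))
            assert tk <= snk <= dc <= lsd


class TestRelationInvariants:
    @pytest.mark.parametrize("test", [lsd_test, tukey_kramer, snk_test, duncan_test])
    def test_symmetric_false_diagonal(self, test, rng):
        s = random_summary(rng)
        rel = test(s).relation
        assert np.array_equal(rel, rel.T)
        assert not rel.diagonal().any()

    def test_order_invariance(self, rng):
        for _ in range(10):
            s = random_summary(rng, k=4, balanced=False)
            perm = rng.permutation(4)
            permuted = ResponseSummary(variable="y",
                                       groups=tuple(s.groups[i] for i in perm))
            for test in (lsd_test, tukey_kramer, snk_test, duncan_test):
                rel = test(s).relation
                rel_p = test(permuted).relation
                assert np.array_equal(rel_p, rel[np.ix_(perm, perm)])


class TestDispatch:
    def test_adjust_only_with_lsd(self):
        anova = anova_from_summary(ARGININE)
        with pytest.raises(ValueError, match="LSD test only"):
            run_posthoc(ARGININE, anova, test="tukey", adjust="holm")

    def test_protected_suppresses_posthoc(self):
        anova = anova_from_summary(ADIPONECTIN)  # omnibus p ~ 0.15
        assert anova.p_value > 0.05
        res = run_posthoc(ADIPONECTIN, anova, test="lsd", protected=True)
        assert not res.relation.any()
        assert res.comparisons == ()

    def test_unknown_test_rejected(self):
        anova = anova_from_summary(ARGININE)
        with pytest.raises(ValueError, match="unknown test"):
            run_posthoc(ARGININE, anova, test="scheffe")
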