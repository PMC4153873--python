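# Methods

## Model and two-step procedure

All computations assume the one-way fixed-effects layout: k treatment
groups whose observations are independent draws from normal distributions
with a common variance σ², differing only in their means. Analysis
proceeds in the classical two steps: an omnibus F-test of "all means
equal", then all-pairwise post-hoc comparisons. By default the post-hoc
step runs *unprotected* (regardless of the omnibus outcome), because a
table generator must letter every row consistently; an opt-in
`protected=True` suppresses the pairwise test when the omnibus p exceeds
α, reproducing the textbook protected procedure.

## ANOVA from summary statistics

Both input paths share one computation. Raw columns are first reduced to
per-group (nᵢ, mᵢ, sᵢ) with the n−1 sample SD; rows with a missing factor
or response value are dropped (empty cells in workbooks; empty fields or
the usual NA tokens in CSV). From summaries:

- grand mean m̄ = Σnᵢmᵢ/N, SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sᵢ²,
  F = MSB/MSW, p = upper tail of F(k−1, N−k).
- SEM input is converted by sᵢ = SEMᵢ·√nᵢ exactly, with no small-sample
  correction (the standard definition).
- pooled SEM = √(MSE/n_h), n_h the common n when balanced, else the
  harmonic mean of the nᵢ — consistent with the range tests' convention.
- Degenerate inputs: all SDs zero with equal means reports F undefined
  (NaN) with p = 1 and a warning; all SDs zero with unequal means is an
  error ("zero within-group variance"). Constant columns must not crash a
  batch table run, but a significance claim from zero variance would be
  meaningless.

All arithmetic is double precision; rounding happens only in the render
layer.

## Post-hoc tests

Let MSE = MSW on ν = N−k df, and order means descending (ties broken by
input order; equal means produce zero ranges, so decisions are
unaffected).

- **LSD**: t = (mᵢ−mⱼ)/√(MSE(1/nᵢ+1/nⱼ)), two-sided p on t(ν). The family
  of k(k−1)/2 raw p-values may be Bonferroni (min(1, m·p)) or Holm
  (step-down with running maximum) adjusted; significance is
  p_adjusted ≤ α.
- **Tukey-Kramer**: q = |mᵢ−mⱼ|/√((MSE/2)(1/nᵢ+1/nⱼ)); p is the upper
  tail of the studentized range with parameters (k, ν). The Kramer
  standard error is the conventional unbalanced generalization.
- **SNK / Duncan**: for a pair spanning r ordered means, the critical
  range is q_{α_r}(r, ν)·√(MSE/n_h) with n_h the harmonic mean of the
  group sizes inside the span. SNK uses α_r = α; Duncan uses the
  protection level α_r = 1−(1−α)^{r−1}, which makes its critical ranges
  no larger than SNK's and its rejections a superset. Spans are examined
  widest-first with blocking: when a span's extreme difference fails its
  critical range, every pair inside is declared not significant untested.
  The normative output of these stepwise tests is the decision plus the
  critical range; the attached per-pair p (the span-r range tail) is
  informational and not FWER-calibrated, since stepwise procedures define
  no single adjusted p.

On the decision level the tests order as Tukey-Kramer ⊆ SNK ⊆ Duncan ⊆
unadjusted LSD (most to least conservative), which the suite verifies on
random balanced inputs.

## Compact letter display

Insert-and-absorb: start with one class containing all groups; for each
significant pair (processed in fixed positional order, for determinism),
duplicate every class containing both members, delete one member from
each copy, then absorb any class that is a subset of another. The result
is sound by construction — significant pairs share no letter,
non-significant pairs share at least one — and absorption guarantees no
nested classes. No letter-minimization beyond absorption is attempted;
absorption alone already guarantees correctness.

Letter *names* are presentation only. Published tables are not consistent
about whether 'a' marks the largest or smallest mean, so the canonical
comparison object is the induced partition (`letters_to_partition`); the
renderer attaches 'a' to the class containing the largest mean.

## Input handling

Supported formats are `.xlsx` workbooks and single-sheet `.csv`; legacy
`.xls` is rejected with a pointer to re-save as `.xlsx`. The data block
is located as the bounding box of non-empty cells; an entirely empty row
or column strictly inside that box means two disjoint blocks and is an
error with coordinates, never a guess. The first row of the block must
name every column. Summary sheets use a documented layout: first column =
group label, then one (mean, dispersion) column pair per response, the
pair's first header naming the response. Whether dispersions are SD or
SEM is a user declaration, never auto-detected. Sample sizes for summary
data are supplied as a single balanced value or one value per group in
file order. Variable names containing spaces are a hard error (failing
fast beats mangling); names over 10 characters get a warning suggesting a
descriptive abbreviation but are never truncated.

## Rendering

Two table formats: per-group SEM (cells "mean ± SEM" with superscript
letters) and pooled SEM (mean-only cells plus one √(MSE/n) column per
row). A row whose letter display has a single class carries no
superscripts. Display precision echoes the number of decimals the source
printed (recorded per group at parse time; raw data default to 2,
overridable); rounding is half-away-from-zero and happens only here. The
RTF writer emits a minimal RTF 1.x document — `\trowd`/`\cell` table
structure, bold header, `{\super …}` letters, ASCII-escaped non-ASCII —
whose bytes are a pure function of the table, so identical inputs give
byte-identical files. A deliberately minimal reader recovers cell texts
from exactly this dialect for round-trip verification; it is not a
general RTF parser. The footnote follows the conventional form "Means in
a row without a common superscript letter differ (P < α)", extended with
the test name for reproducibility.

## Synthetic data generator

The generator realizes exactly the model the ANOVA assumes: response =
group effect + Normal(0, σ), common σ, fixed seed. Defaults emulate a
small toy workbook — factor `group`, levels A–D, six responses V1–V6,
n = 10 per group, σ = 1, true means spread 0 to 1.05σ (a moderate effect
that typically separates extreme groups at n = 10 without saturating).
Summary workbooks default to two responses over four levels L1–L4.
Workbook bytes are deterministic per seed (fixed document timestamps and
zip metadata), and a flat key=value sidecar records true means, σ and the
exact sample moments written, so tests can verify the read path to
machine precision. What the generator does **not** emulate: non-normal
errors, heteroscedasticity, correlated responses, or outliers — passing
tests therefore demonstrate correctness of the computations under the
model's assumptions, not robustness of the tests to their violation.

## Reference-table reproduction

The packaged 11-row reference table (plasma metabolites/hormones of ZDF
rats under oral IFNT doses 0/4/8 μg/kg, means ± SEM, n = 6) is rebuilt
from its printed summary statistics at α = 0.05. SNK, Duncan and
unadjusted LSD reproduce all 11 printed letter partitions; the omnibus p
is below 0.05 exactly for the nine lettered rows and above it for the two
unlettered ones (insulin, adiponectin). Tukey-Kramer, being more
conservative, reproduces 9 of 11: it letters the cholesterol and
free-fatty-acids rows a/ab/b instead of the printed a/a/b (pairwise p ≈
0.068 and 0.059 — both just over the boundary under exact reconstruction
from the rounded, printed SEMs). The pooled-SEM column of the pooled
format follows √(MSE/n) computed from the printed SEMs; a source table's
printed pooled SEMs may differ slightly when they were computed from
unpublished raw data.

## Numerical and scale choices

- Studentized-range quantiles (`scipy.stats.studentized_range.ppf`) are
  memoized on (α_r, r, ν); they dominate runtime otherwise (~0.1 s per
  distinct triple).
- Property tests draw group sizes from a small grid so that cache stays
  effective; the power-ordering check uses 200 random balanced rows, the
  letter-display oracle runs exhaustively for k ≤ 4 (all 2^C(k,2)
  relations) plus 1000 random relations for k ∈ {5, 6, 7}, and the null
  calibration uses 500 simulated datasets (k = 3, n = 10) — sizes chosen
  to give stable checks in well under the times stated alongside them.
- The null-calibration rate estimate has binomial SD ≈ 0.0097 at 500
  draws, so individual runs scatter about 0.05 accordingly.
- Holm adjustment enforces the running maximum and caps at 1; input order
  is restored with a stable argsort, so ties are handled deterministically.

## Limitations

One factor only — no factorial, repeated-measures or Welch-type
unequal-variance ANOVA, and no normality or homoscedasticity diagnostics:
the user is responsible for checking the model's assumptions. General
contrasts, Dunnett/Scheffé tests and FDR-type adjustments are out of
scope. Letter displays beyond ~26 classes are impractical. DOCX/ODT
output and table transposition are left to the word processor.
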