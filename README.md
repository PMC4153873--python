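# anovatab

Publication tables in agricultural, nutritional and biomedical journals
typically report each response variable as per-group means ± SEM with
superscript letters marking which treatment groups differ: groups that
share a letter are not significantly different. Producing those tables by
hand — running a one-way ANOVA per row, a post-hoc multiple comparison
test, translating the pairwise decisions into letters, and typesetting
the superscripts — is tedious and error-prone, and is impossible with
most point-and-click tools when only the *summary* statistics (n, mean,
SD or SEM per group) survive, as when checking a published table.

`anovatab` automates the whole workflow as a Python library with a thin
command-line interface:

- **One-way ANOVA from raw or summary data.** Raw columns are reduced to
  per-group (nᵢ, mᵢ, sᵢ) and both paths share one computation:
  SSB = Σ nᵢ(mᵢ − m̄)², SSW = Σ (nᵢ−1)sᵢ², F = MSB/MSW on (k−1, N−k)
  degrees of freedom. SEM input is converted via sᵢ = SEMᵢ·√nᵢ.
- **Post-hoc tests.** Fisher LSD (pairwise t on the pooled MSE, with
  optional Bonferroni or Holm p-adjustment), Tukey-Kramer
  (q = |mᵢ−mⱼ|/√((MSE/2)(1/nᵢ+1/nⱼ)) against the studentized range),
  Student-Newman-Keuls and Duncan multiple range tests (critical range
  q_{α_r}(r, df)·√(MSE/n_h) for a pair spanning r ordered means, with
  widest-first blocking; Duncan relaxes the protection level to
  α_r = 1 − (1−α)^{r−1}).
- **Compact letter display.** The insert-and-absorb algorithm converts
  the pairwise significance relation into letters; sharing a letter ⇔
  not significantly different.
- **Publication-ready output.** RTF tables (opening directly in Word or
  any RTF reader) in the two standard formats — mean ± SEM per cell, or
  mean-only cells with one pooled SEM (√(MSE/n)) column — plus TSV and
  Markdown mirrors.
- **Workbook input.** `.xlsx` and `.csv`, raw or summary layout, one
  dataset per sheet for batch processing; empty cells are missing values
  and the data block need not start at cell A1.

## Worked example

Check the statistics behind one published row, from nothing but what the
journal printed (`examples/check_one_published_row.py` — plasma arginine,
μM, under three oral IFNT doses, means ± SEM, n = 6):

```python
from anovatab import GroupSummary, ResponseSummary, anova_from_summary, snk_test

row = ResponseSummary(variable="Arginine", groups=tuple(
    GroupSummary(label=lab, n=6, mean=m, dispersion=s, dispersion_kind="sem")
    for lab, m, s in [("0", 110, 4), ("4", 115, 5), ("8", 149, 6)]))
anova = anova_from_summary(row)
```

prints

```
omnibus: F(2,15) = 17.545, p = 1.18e-04, MSE = 154.0, pooled SEM = 5.07
  8 vs 0 (span 3): |diff| =  39.0, critical range = 18.61 -> differ
  8 vs 4 (span 2): |diff| =  34.0, critical range = 15.27 -> differ
  4 vs 0 (span 2): |diff| =   5.0, critical range = 15.27 -> do not differ
```

The omnibus test rejects equality of the three dose means (F on 2 and 15
df, p ≈ 1.2 × 10⁻⁴). The SNK ranges then show the 8 μg/kg dose differs
from both lower doses while 0 and 4 μg/kg do not differ — exactly the
b/b/a superscripts the source table prints.

To produce a whole table at once from the shell (here a workbook whose
sheet has a factor column `group` and response columns `V1`–`V6`):

```sh
anovatab single_data.xlsx --scenario S1 --factor group --test snk --tsv
```

writes `single_data.rtf` (and `.tsv`), one row per response, with a
footnote of the form "Means in a row without a common superscript letter
differ (P < 0.05), as analyzed by one-way ANOVA followed by the SNK
test." Summary workbooks use `--scenario S3/S4` with `--dispersion
sd|sem` and `--sizes "15"` (balanced) or `--sizes "15 14 15 16"`
(unbalanced, in file order). See `examples/` for the other capabilities:
rebuilding the packaged 11-row reference table from its summary
statistics, the full raw-workbook pipeline, and a power comparison of
the four tests on a borderline row.

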