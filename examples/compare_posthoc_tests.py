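"""How the four post-hoc tests rank in power on one borderline row.

The total-cholesterol row (5.18/4.94/4.23 mM, SEMs 0.23/0.24/0.13, n = 6)
sits near the significance boundary: the stepwise and LSD tests separate
the low-dose pair from the high dose, while the more conservative
Tukey-Kramer leaves the middle group ambiguous (it shares a letter with
both neighbours).
"""

from anovatab import GroupSummary, ResponseSummary, analyze_response

cholesterol = ResponseSummary(variable="Cholesterol", groups=tuple(
    GroupSummary(label=lab, n=6, mean=m, dispersion=s, dispersion_kind="sem",
                 display_precision=2)
    for lab, m, s in [("0", 5.18, 0.23), ("4", 4.94, 0.24), ("8", 4.23, 0.13)]))

for test in ("tukey", "snk", "duncan", "lsd"):
    r = analyze_response(cholesterol, test=test, alpha=0.05)
    sig = sorted("-".join(c.pair) for c in r.mcp.comparisons if c.significant)
    print(f"{test:>7}: letters {'/'.join(r.letters.letters):7}  "
          f"significant pairs: {sig}")
print("\nDecision-level power ordering: Tukey-Kramer <= SNK <= Duncan <= LSD.")
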