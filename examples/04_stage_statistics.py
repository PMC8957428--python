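"""Stage-comparison statistics: ANOVA from raw data and from summaries.

One-way ANOVA across training stages works identically from raw per-subject
values or from published (n, mean, SD) group summaries.  Also shows the
four-level resting-potential banding of the functional state.
"""

from hrvcdet import (
    GroupSummary,
    anova_from_summary,
    anova_oneway,
    classify_resting_potential,
)

raw = anova_oneway([[1, 2, 3], [4, 5, 6]])
print(f"raw-data ANOVA:   F = {raw.F:.1f}, df = ({raw.df_between}, {raw.df_within}), p = {raw.p:.4f}")

summ = anova_from_summary(
    [GroupSummary("g1", n=3, mean=2.0, sd=1.0), GroupSummary("g2", n=3, mean=5.0, sd=1.0)]
)
print(f"summary ANOVA:    F = {summ.F:.1f}  (identical by construction)")

print("\nresting potential banding (mV -> functional state):")
for mv in (-35, -10, 0, 20, 46, 47, 60):
    print(f"  {mv:>4} mV -> {classify_resting_potential(mv).name}")
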