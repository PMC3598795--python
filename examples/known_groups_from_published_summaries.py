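"""Known-groups validity recomputed from printed group summaries.

A published comparison table prints, per scale, each health-status group's
n, mean and SD next to a p-value and an effect size.  Those summaries are
sufficient statistics for the one-way ANOVA, so the whole row can be
re-derived: grand mean, SS decomposition, F, p and the correlation ratio
eta = sqrt(SSb / (SSb + SSw)).
"""

from psychfield import GroupSummary, anova_from_summary, effect_size_label
from psychfield.known_groups import GROUP_LABELS, format_p

# typed straight from a published comparison: (n, mean, sd) per group
rows = {
    "Pain and Hurt": [(46, 74.09, 28.45), (43, 58.53, 25.10), (38, 23.25, 22.77)],
    "Fatigue": [(46, 63.04, 27.81), (42, 58.93, 24.72), (36, 28.94, 19.05)],
    "Total Score": [(47, 74.37, 14.03), (46, 64.63, 15.64), (41, 48.37, 13.60)],
}

for scale, triples in rows.items():
    row = anova_from_summary(
        [GroupSummary(lab, n, m, sd) for lab, (n, m, sd) in zip(GROUP_LABELS, triples)]
    )
    print(
        f"{scale:15s}  grand mean {row.grand_mean:6.2f}  "
        f"F({row.df_between},{row.df_within}) = {row.f:6.2f}  "
        f"p = {format_p(row.p):6s}  eta = {row.eta:.2f} ({effect_size_label(row.eta)})"
    )

print(
    "\nEta near 0.6 (medium, approaching large) for pain-related scales "
    "says self-reported health status separates respondents most strongly "
    "on pain; the Total Score's eta of ~0.59 supports using the overall "
    "score to distinguish health strata."
)
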