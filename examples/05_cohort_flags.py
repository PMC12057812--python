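"""Cohort arithmetic: normalized expression and generic/discriminative flags.

Coverage is normalized per sample as log10(1 + CPM).  Targets broadly
present (>20% prevalence) and expressed (mean > 0.1) in BOTH groups are
'generic' (removed from analyses); among the rest, a two-fold mean
difference with detection in >=3 individuals of the enriched group marks a
target 'discriminative'.
"""

from nulloscan.cohort import SampleExpression, cohort_summary, normalized_expression

print(f"log10(1+CPM) of 10 reads in a 1M-read library: {normalized_expression(10, 10**6):.4f}")

samples = [
    SampleExpression("case1", "case", 1_000_000, {"MUT_A": 50, "MUT_B": 5}),
    SampleExpression("case2", "case", 1_000_000, {"MUT_A": 40, "MUT_B": 4}),
    SampleExpression("case3", "case", 1_000_000, {"MUT_A": 60, "MUT_B": 3}),
    SampleExpression("ctrl1", "control", 1_000_000, {"MUT_A": 45}),
    SampleExpression("ctrl2", "control", 1_000_000, {"MUT_A": 55}),
    SampleExpression("ctrl3", "control", 1_000_000, {}),
]
print(cohort_summary(samples).to_string(index=False))

# MUT_A is expressed in everyone -> generic (uninformative, removed).
# MUT_B appears only in the three cases -> case-enriched discriminative.
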