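"""Locate the net-benefit curve intersection and compare it with Youden.

NB0(t) = TP/n - TN/n * t/(1-t) and NB1(t) = FP/n - FN/n * t/(1-t) are
swept over a threshold grid; the x-coordinate of their first crossing is
taken as the decision threshold.  The paired McNemar test then asks
whether the two strategies classify subjects differently.
"""

import warnings

from nbroc import compare_strategies, generate_cohort, tail_concentrated_spec

cohort = generate_cohort(tail_concentrated_spec(n=20_000, seed=7))
with warnings.catch_warnings():
    warnings.simplefilter("ignore")  # multiple nearby crossings are reported
    report = compare_strategies(cohort)

print(report.to_markdown())
nb = report.selections["nb_intersection"]
print(f"\nall crossings found: {[round(t, 5) for t in nb.crossings]}")
print(f"NB0 at the crossing (criterion value): {nb.criterion_value:.5f}")
# At ~3% prevalence the crossing sits in the high-specificity tail: the
# weighted true-negative term dominates NB0 everywhere else, so the
# intersection threshold is MORE specific and LESS sensitive than Youden's.
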