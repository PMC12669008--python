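"""Select decision thresholds on a synthetic screening cohort.

Generates an imbalanced cohort (2.9% pathology) whose normal-class scores
are concentrated near zero, then picks a cut-off with each classical
strategy.  Printed lines show the chosen threshold, the criterion value
the strategy optimized, and the sensitivity/specificity it buys.
"""

from nbroc import (
    closest_topleft_threshold,
    fixed_sensitivity_threshold,
    generate_cohort,
    roc_curve,
    tail_concentrated_spec,
    youden_threshold,
)

cohort = generate_cohort(tail_concentrated_spec(n=20_000, seed=7))
roc = roc_curve(cohort)
print(f"cohort: n={cohort.n}, prevalence={cohort.prevalence:.4f}, AUC={roc.auc:.3f}")

for sel in (
    youden_threshold(cohort, roc),
    closest_topleft_threshold(cohort, roc),
    fixed_sensitivity_threshold(cohort, 0.95, roc),
):
    print(
        f"{sel.method:>18}: t={sel.threshold:.5f} criterion={sel.criterion_value:.4f} "
        f"Se={sel.metrics.se:.3f} Sp={sel.metrics.sp:.3f}"
    )
# Higher sensitivity floors push the threshold down and specificity with it;
# Youden balances the two error rates instead.
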