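"""Aggregate reported operating points across AI service versions.

The seven reported (Se, Sp, Acc) cells per thresholding strategy are
averaged with mean/min/max, printed as whole percents: switching from
Youden to net-benefit thresholds raised mean sensitivity 64% -> 87%
(max 99%) and lowered mean specificity 80% -> 49% (min 48%) on the
source screening cohort.
"""

from nbroc import summarize_across_models
from nbroc.published import published_operating_points

table = published_operating_points()
summary = summarize_across_models(table)
cols = ["strategy", "metric", "n_models", "mean_pct", "min_pct", "max_pct"]
print(summary[cols].to_string(index=False))
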