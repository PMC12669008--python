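"""End-to-end CSV pipeline with BI-RADS labels.

Writes a small CSV with BI-RADS categories, loads it (categories 1-3
become "normal", 4-6 "pathology", 0 is excluded with accounting), and
evaluates a fixed threshold.
"""

import tempfile
from pathlib import Path

from nbroc import confusion_at_threshold, metrics, read_cohort

csv_text = """score,birads
0.92,5
0.81,4
0.40,3
0.15,2
0.07,1
0.55,0
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "cohort.csv"
    path.write_text(csv_text)
    result = read_cohort(path)

print(f"loaded n={result.cohort.n}, excluded {result.n_excluded} "
      f"(rows {list(result.excluded_rows)}) as BI-RADS 0")
counts = confusion_at_threshold(result.cohort, 0.5)
m = metrics(counts)
print(f"at t=0.5: TP={counts.tp} FP={counts.fp} TN={counts.tn} FN={counts.fn} "
      f"-> Se={m.se:.2f} Sp={m.sp:.2f} Acc={m.acc:.2f}")
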