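"""Reported operating points of deployed mammography AI services.

Seven evaluations (three commercial AI services, some with multiple
versions) on a Moscow population screening cohort of 663,606 mammography
exams (19,441 pathology, 2.9% prevalence), each reported at two decision
thresholds: the Youden-index optimum and the net-benefit-curve
intersection.  These printed per-version sensitivity / specificity /
accuracy cells are the inputs from which the cross-model aggregates
(mean, min, max per strategy) are recomputed; the underlying per-subject
data are not public.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import ScoredCohort

__all__ = [
    "SCREENING_N_NORMAL",
    "SCREENING_N_PATHOLOGY",
    "published_operating_points",
    "screening_label_cohort",
]

#: Class counts of the screening cohort the services were evaluated on.
SCREENING_N_PATHOLOGY = 19_441
SCREENING_N_NORMAL = 644_165

_VERSIONS = ["AI1_v1", "AI1_v2", "AI1_v3", "AI2_v1", "AI2_v2", "AI2_v3", "AI3_v1"]

_YOUDEN = {
    "threshold": [0.57, 0.78, 0.79, 0.44, 0.42, 0.44, 0.20],
    "se": [0.53, 0.68, 0.72, 0.58, 0.66, 0.60, 0.68],
    "sp": [0.84, 0.81, 0.84, 0.84, 0.76, 0.79, 0.75],
    "acc": [0.83, 0.81, 0.84, 0.83, 0.75, 0.78, 0.75],
}

_NET_BENEFIT = {
    "threshold": [0.17, 0.51, 0.35, 0.21, 0.21, 0.19, 0.60],
    "se": [0.80, 0.88, 0.91, 0.85, 0.84, 0.99, 0.85],
    "sp": [0.49, 0.49, 0.48, 0.51, 0.50, 0.50, 0.49],
    "acc": [0.50, 0.50, 0.50, 0.52, 0.51, 0.51, 0.50],
}


def published_operating_points() -> pd.DataFrame:
    """Tidy table of the reported per-version operating points.

    Columns: ``model`` (service/version tag), ``strategy`` ("youden" or
    "nb_intersection"), ``threshold``, ``se``, ``sp``, ``acc`` — directly
    consumable by :func:`nbroc.evaluation.summarize_across_models`.
    """
    frames = []
    for strategy, cells in (("youden", _YOUDEN), ("nb_intersection", _NET_BENEFIT)):
        frames.append(
            pd.DataFrame(
                {
                    "model": _VERSIONS,
                    "strategy": strategy,
                    "threshold": cells["threshold"],
                    "se": cells["se"],
                    "sp": cells["sp"],
                    "acc": cells["acc"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def screening_label_cohort() -> ScoredCohort:
    """Label structure of the screening cohort (scores are placeholders).

    Builds a cohort with the published class counts so that prevalence-type
    quantities can be computed through the ordinary cohort API.  Scores
    carry no information (0.0 for normals, 1.0 for pathology) because the
    per-subject scores are not public; only label-derived quantities are
    meaningful on this object.
    """
    n = SCREENING_N_PATHOLOGY + SCREENING_N_NORMAL
    labels = np.zeros(n, dtype=np.int8)
    labels[:SCREENING_N_PATHOLOGY] = 1
    return ScoredCohort(labels.astype(float), labels)
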