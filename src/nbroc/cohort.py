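"""Scored screening cohorts: data model, BI-RADS binarization, CSV I/O.

A cohort is the universal input of this package: one classifier score in
[0, 1] ("pathology probability") and one binary ground-truth label per
subject.  Labels may come directly as {0, 1} or be derived from BI-RADS
categories, where 1-3 map to "normal" (0), 4-6 to "pathology" (1), and
category 0 — which flags an uninterpretable exam — is excluded with the
exclusion counted rather than silently dropped.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EXCLUDED",
    "CohortError",
    "ScoredCohort",
    "CohortLoadResult",
    "binarize_birads",
    "class_prevalence",
    "read_cohort",
    "write_cohort",
]


class CohortError(ValueError):
    """Raised for invalid cohort data (bad scores, labels, or file contents)."""


class _Excluded:
    """Sentinel for records removed from a cohort (BI-RADS 0)."""

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "EXCLUDED"


#: Marker returned by :func:`binarize_birads` for BI-RADS category 0.
EXCLUDED = _Excluded()


@dataclasses.dataclass(frozen=True)
class ScoredCohort:
    """Per-subject classifier scores in [0, 1] with binary truth labels.

    Parameters
    ----------
    scores
        Classifier "pathology probability" per subject, each in [0, 1]
        (0 and 1 inclusive: deployed models may saturate).
    labels
        Ground truth per subject; 1 = pathology, 0 = normal.
    ids
        Optional opaque subject identifiers, same length as ``scores``.
    """

    scores: np.ndarray
    labels: np.ndarray
    ids: tuple | None = None

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        labels = np.asarray(self.labels)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 1 or labels.ndim != 1:
            raise CohortError("scores and labels must be one-dimensional")
        if scores.size != labels.size:
            raise CohortError(
                f"scores (n={scores.size}) and labels (n={labels.size}) "
                "must have equal length"
            )
        if scores.size < 1:
            raise CohortError("cohort must contain at least one record")
        if np.isnan(scores).any():
            bad = np.flatnonzero(np.isnan(scores))
            raise CohortError(f"missing (NaN) scores at rows {bad[:10].tolist()}")
        if (scores < 0).any() or (scores > 1).any():
            bad = np.flatnonzero((scores < 0) | (scores > 1))
            raise CohortError(
                f"scores outside [0, 1] at rows {bad[:10].tolist()} "
                f"(first offending value {scores[bad[0]]!r})"
            )
        if not np.isin(labels, (0, 1)).all():
            bad = np.flatnonzero(~np.isin(labels, (0, 1)))
            raise CohortError(
                f"labels outside {{0, 1}} at rows {bad[:10].tolist()} "
                f"(first offending value {labels[bad[0]]!r})"
            )
        object.__setattr__(self, "labels", labels.astype(np.int8))
        if self.ids is not None:
            ids = tuple(self.ids)
            if len(ids) != scores.size:
                raise CohortError("ids must match scores in length")
            object.__setattr__(self, "ids", ids)

    @property
    def n(self) -> int:
        return int(self.scores.size)

    @property
    def n_pos(self) -> int:
        return int(self.labels.sum())

    @property
    def n_neg(self) -> int:
        return self.n - self.n_pos

    @property
    def prevalence(self) -> float:
        return self.n_pos / self.n

    def positive_scores(self) -> np.ndarray:
        return self.scores[self.labels == 1]

    def negative_scores(self) -> np.ndarray:
        return self.scores[self.labels == 0]

    def shuffled(self, rng: np.random.Generator) -> "ScoredCohort":
        """Return the same cohort with record order permuted."""
        order = rng.permutation(self.n)
        ids = None if self.ids is None else tuple(self.ids[i] for i in order)
        return ScoredCohort(self.scores[order], self.labels[order], ids)

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame({"score": self.scores, "label": self.labels})
        if self.ids is not None:
            frame.insert(0, "id", list(self.ids))
        return frame


def binarize_birads(birads: int):
    """Map a BI-RADS category to a binary pathology label.

    Categories 1-3 → 0 (normal; category 3 carries <2% malignancy
    likelihood), 4-6 → 1 (pathology), 0 → :data:`EXCLUDED` (the exam could
    not be assessed and the record is dropped from the cohort).

    Raises
    ------
    CohortError
        If ``birads`` is not an integer in {0..6}.
    """
    try:
        value = int(birads)
    except (TypeError, ValueError):
        raise CohortError(f"BI-RADS category must be an integer, got {birads!r}")
    if value != birads or not 0 <= value <= 6:
        raise CohortError(f"BI-RADS category {birads!r} outside {{0..6}}")
    if value == 0:
        return EXCLUDED
    return 1 if value >= 4 else 0


def class_prevalence(cohort: ScoredCohort) -> float:
    """Fraction of pathology (label 1) records in the cohort."""
    return cohort.prevalence


class CohortLoadResult(NamedTuple):
    """A parsed cohort plus the exclusion accounting from BI-RADS 0 rows."""

    cohort: ScoredCohort
    n_excluded: int
    excluded_rows: tuple

    def exclusion_summary(self) -> dict:
        return {
            "n_records": self.cohort.n,
            "n_excluded": self.n_excluded,
            "excluded_rows": list(self.excluded_rows),
        }


def read_cohort(
    path,
    *,
    score_col: str = "score",
    label_col: str = "label",
    birads_col: str = "birads",
    id_col: str | None = None,
) -> CohortLoadResult:
    """Read a scored cohort from a headed CSV file.

    The file must contain ``score_col`` plus either ``label_col`` (binary
    labels used as-is) or ``birads_col`` (categories run through
    :func:`binarize_birads`; BI-RADS 0 rows are excluded and reported).
    Row order is preserved.  Reported row numbers are zero-based data rows
    (header not counted).
    """
    path = Path(path)
    try:
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise CohortError(f"{path}: file is empty")
    if frame.shape[0] == 0:
        raise CohortError(f"{path}: no data rows")
    if score_col not in frame.columns:
        raise CohortError(f"{path}: missing required score column {score_col!r}")
    has_label = label_col in frame.columns
    has_birads = birads_col in frame.columns
    if not has_label and not has_birads:
        raise CohortError(
            f"{path}: need a label column {label_col!r} or a BI-RADS column "
            f"{birads_col!r}; found {list(frame.columns)}"
        )

    scores = pd.to_numeric(frame[score_col], errors="coerce").to_numpy(float)
    bad = np.flatnonzero(np.isnan(scores))
    if bad.size:
        raise CohortError(
            f"{path}: non-numeric or missing score at row {bad[0]} "
            f"(value {frame[score_col].iloc[bad[0]]!r})"
        )

    excluded_rows: list[int] = []
    if has_label:
        labels = frame[label_col].to_numpy()
    else:
        mapped = []
        for row, value in enumerate(frame[birads_col]):
            try:
                result = binarize_birads(value)
            except CohortError as exc:
                raise CohortError(f"{path}: row {row}: {exc}") from exc
            if result is EXCLUDED:
                excluded_rows.append(row)
            else:
                mapped.append(result)
        keep = np.setdiff1d(np.arange(len(frame)), excluded_rows)
        scores = scores[keep]
        frame = frame.iloc[keep]
        labels = np.asarray(mapped)
        if labels.size == 0:
            raise CohortError(f"{path}: all rows excluded (BI-RADS 0)")

    ids = None if id_col is None else tuple(frame[id_col])
    try:
        cohort = ScoredCohort(scores, labels, ids)
    except CohortError as exc:
        raise CohortError(f"{path}: {exc}") from exc
    return CohortLoadResult(cohort, len(excluded_rows), tuple(excluded_rows))


def write_cohort(cohort: ScoredCohort, path) -> None:
    """Write a cohort as CSV in the same schema :func:`read_cohort` reads.

    Scores are written with :func:`repr`-level precision so that a
    write/read round-trip reproduces them bit-exactly.
    """
    path = Path(path)
    frame = cohort.to_frame()
    frame["score"] = [repr(float(s)) for s in cohort.scores]
    frame.to_csv(path, index=False)


def write_exclusion_summary(result: CohortLoadResult, path) -> None:
    """Persist the exclusion accounting of a load as JSON."""
    Path(path).write_text(json.dumps(result.exclusion_summary(), indent=2))
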