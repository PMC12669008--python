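import numpy as np
import pytest

from nbroc import ScoredCohort, generate_cohort, tail_concentrated_spec


@pytest.fixture
def six_record_cohort() -> ScoredCohort:
    """Positives score {0.8, 0.6, 0.4}, negatives {0.7, 0.3, 0.1}."""
    return ScoredCohort(
        scores=[0.8, 0.6, 0.4, 0.7, 0.3, 0.1],
        labels=[1, 1, 1, 0, 0, 0],
    )


@pytest.fixture
def separable_cohort() -> ScoredCohort:
    """Perfectly separated classes: positives at 0.9, negatives at 0.1."""
    return ScoredCohort(
        scores=[0.9, 0.9, 0.9, 0.1, 0.1, 0.1, 0.1],
        labels=[1, 1, 1, 0, 0, 0, 0],
    )


@pytest.fixture(scope="session")
def tail_cohort():
    """Fixed-seed imbalanced screening cohort whose NB curves cross."""
    return generate_cohort(tail_concentrated_spec(n=20_000, prevalence=0.029, seed=7))


def random_cohort(rng: np.random.Generator, n_max: int = 200) -> ScoredCohort:
    """Small random cohort with both classes present and tied scores likely."""
    n = int(rng.integers(4, n_max + 1))
    # Coarse score grid encourages ties, exercising the >= rule.
    scores = rng.integers(0, 21, n) / 20.0
    labels = rng.integers(0, 2, n)
    if labels.sum() == 0:
        labels[int(rng.integers(n))] = 1
    if labels.sum() == n:
        labels[int(rng.integers(n))] = 0
    return ScoredCohort(scores, labels)
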