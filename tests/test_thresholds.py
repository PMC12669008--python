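import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nbroc import (
    LossProfile,
    MultipleIntersectionsWarning,
    NoIntersectionError,
    ScoredCohort,
    closest_topleft_threshold,
    confusion_at_threshold,
    default_nb_grid,
    fixed_sensitivity_threshold,
    fixed_specificity_threshold,
    generate_cohort,
    metrics,
    nb_intersection_threshold,
    net_benefit_curves,
    preset_service_profiles,
    probability_threshold_from_losses,
    tail_concentrated_spec,
    vickers_net_benefit,
    youden_threshold,
)
from conftest import random_cohort


def brute_force_best(cohort, objective):
    """Exhaustive search over all observed cut-offs; returns best value."""
    best = None
    for t in np.unique(cohort.scores):
        m = metrics(confusion_at_threshold(cohort, float(t)))
        value = objective(m)
        if best is None or value > best + 1e-15:
            best = value
    return best


class TestLossThreshold:
    @pytest.mark.parametrize("L,P,expected", [(1, 4, 0.2), (2, 2, 0.5), (3, 1, 0.75)])
    def test_threshold_from_loss_profit_ratio(self, L, P, expected):
        assert probability_threshold_from_losses(LossProfile(L, P)) == pytest.approx(
            expected
        )

    @pytest.mark.parametrize("L,P", [(0, 1), (1, 0), (-1, 1)])
    def test_non_positive_losses_rejected(self, L, P):
        with pytest.raises(ValueError):
            LossProfile(L, P)


class TestVickersNetBenefit:
    def test_unit_weight_at_half(self):
        cohort = ScoredCohort(
            [0.9] * 30 + [0.8] * 10 + [0.1] * 60, [1] * 30 + [0] * 10 + [0] * 60
        )
        assert vickers_net_benefit(cohort, 0.5) == pytest.approx((30 - 10) / 100)

    def test_six_record_hand_value(self, six_record_cohort):
        assert vickers_net_benefit(six_record_cohort, 0.5) == pytest.approx(1 / 6)

    def test_small_pt_approaches_prevalence(self, six_record_cohort):
        assert vickers_net_benefit(six_record_cohort, 1e-9) == pytest.approx(
            0.5, abs=1e-6
        )

    @pytest.mark.parametrize("pt", [0.0, 1.0, -0.2])
    def test_domain_error_outside_open_interval(self, six_record_cohort, pt):
        with pytest.raises(ValueError):
            vickers_net_benefit(six_record_cohort, pt)

    @given(st.integers(0, 2**32 - 1), st.floats(0.05, 0.95))
    @settings(max_examples=40, deadline=None)
    def test_matches_independent_recomputation(self, seed, pt):
        cohort = random_cohort(np.random.default_rng(seed))
        tp = np.sum((cohort.scores >= pt) & (cohort.labels == 1))
        fp = np.sum((cohort.scores >= pt) & (cohort.labels == 0))
        expected = tp / cohort.n - fp / cohort.n * pt / (1 - pt)
        assert vickers_net_benefit(cohort, pt) == pytest.approx(expected)


class TestClassicalSelectors:
    def test_youden_on_six_records(self, six_record_cohort):
        sel = youden_threshold(six_record_cohort)
        assert sel.threshold == pytest.approx(0.4)
        assert sel.criterion_value == pytest.approx(2 / 3)

    def test_youden_perfect_separation(self):
        cohort = ScoredCohort([0.9, 0.7, 0.6, 0.5, 0.4, 0.2], [1, 1, 1, 0, 0, 0])
        sel = youden_threshold(cohort)
        assert sel.threshold == pytest.approx(0.6)
        assert sel.criterion_value == pytest.approx(1.0)

    def test_youden_near_zero_on_uninformative_scores(self):
        rng = np.random.default_rng(17)
        scores = rng.random(6000)
        labels = rng.permutation(np.repeat([0, 1], 3000))
        sel = youden_threshold(ScoredCohort(scores, labels))
        assert sel.criterion_value == pytest.approx(0.0, abs=0.06)

    def test_closest_corner_zero_distance_when_separable(self, separable_cohort):
        sel = closest_topleft_threshold(separable_cohort)
        assert sel.criterion_value == pytest.approx(0.0)
        assert sel.metrics.se == 1.0 and sel.metrics.sp == 1.0

    def test_fixed_sensitivity_full_recall(self, six_record_cohort):
        sel = fixed_sensitivity_threshold(six_record_cohort, 1.0)
        assert sel.threshold == pytest.approx(0.4)  # min positive score
        assert sel.counts.fn == 0

    def test_fixed_sensitivity_floor_two_thirds(self, six_record_cohort):
        sel = fixed_sensitivity_threshold(six_record_cohort, 0.66)
        assert sel.threshold == pytest.approx(0.6)
        assert sel.metrics.se == pytest.approx(2 / 3)
        assert sel.metrics.sp == pytest.approx(2 / 3)

    def test_fixed_sensitivity_above_step_drops_threshold(self, six_record_cohort):
        sel = fixed_sensitivity_threshold(six_record_cohort, 0.68)
        assert sel.threshold == pytest.approx(0.4)
        assert sel.metrics.se == 1.0

    def test_fixed_specificity_symmetric_variant(self, six_record_cohort):
        sel = fixed_specificity_threshold(six_record_cohort, 0.66)
        # Smallest threshold whose Sp >= 2/3 keeps sensitivity maximal.
        assert sel.metrics.sp >= 2 / 3 - 1e-12
        assert sel.threshold == pytest.approx(0.4)

    @pytest.mark.parametrize("target", [0.0, 1.5, -0.5])
    def test_unreachable_targets_rejected(self, six_record_cohort, target):
        with pytest.raises(ValueError):
            fixed_sensitivity_threshold(six_record_cohort, target)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=60, deadline=None)
    def test_selectors_match_exhaustive_search(self, seed):
        """Criterion optimality is reproducible by brute force (n <= 200)."""
        cohort = random_cohort(np.random.default_rng(seed))
        sel_j = youden_threshold(cohort)
        best_j = brute_force_best(cohort, lambda m: m.se + m.sp - 1)
        assert sel_j.criterion_value == pytest.approx(best_j, abs=1e-12)
        # J at the selected point equals tpr - fpr there.
        m = metrics(confusion_at_threshold(cohort, sel_j.threshold))
        assert sel_j.criterion_value == pytest.approx(m.se - (1 - m.sp), abs=1e-12)

        sel_d = closest_topleft_threshold(cohort)
        best_d = -brute_force_best(
            cohort, lambda m: -np.hypot(1 - m.se, 1 - m.sp)
        )
        assert sel_d.criterion_value == pytest.approx(best_d, abs=1e-12)
        m = metrics(confusion_at_threshold(cohort, sel_d.threshold))
        assert sel_d.criterion_value**2 == pytest.approx(
            (1 - m.se) ** 2 + (1 - m.sp) ** 2, abs=1e-12
        )

    @given(st.integers(0, 2**32 - 1), st.floats(0.1, 1.0))
    @settings(max_examples=40, deadline=None)
    def test_fixed_sensitivity_is_largest_feasible_cutoff(self, seed, target):
        cohort = random_cohort(np.random.default_rng(seed))
        sel = fixed_sensitivity_threshold(cohort, target)
        assert sel.metrics.se >= target - 1e-12
        above = [
            t
            for t in np.unique(cohort.scores)
            if t > sel.threshold
            and metrics(confusion_at_threshold(cohort, float(t))).se
            >= target - 1e-12
        ]
        assert not above


class TestNetBenefitCurves:
    def test_boundary_identities_at_zero(self, six_record_cohort):
        curves = net_benefit_curves(six_record_cohort)
        assert curves.grid[0] == 0.0
        assert curves.nb0[0] == pytest.approx(six_record_cohort.prevalence)
        assert curves.nb1[0] == pytest.approx(1 - six_record_cohort.prevalence)

    def test_unit_weight_at_half(self, six_record_cohort):
        curves = net_benefit_curves(six_record_cohort, np.array([0.5]))
        c = confusion_at_threshold(six_record_cohort, 0.5)
        assert curves.nb0[0] == pytest.approx((c.tp - c.tn) / 6)
        assert curves.nb1[0] == pytest.approx((c.fp - c.fn) / 6)

    def test_grid_values_match_scalar_recomputation(self, six_record_cohort):
        grid = np.arange(0.05, 0.951, 0.05)
        curves = net_benefit_curves(six_record_cohort, grid)
        for i, t in enumerate(grid):
            c = confusion_at_threshold(six_record_cohort, float(t))
            w = t / (1 - t)
            assert curves.nb0[i] == pytest.approx(c.tp / 6 - c.tn / 6 * w)
            assert curves.nb1[i] == pytest.approx(c.fp / 6 - c.fn / 6 * w)

    def test_divergence_toward_one(self, six_record_cohort):
        """Both curves head to large negative values as t nears 1."""
        curves = net_benefit_curves(six_record_cohort)
        assert curves.nb0[-1] < -100
        assert curves.nb1[-1] < -100

    def test_fixed_p0_p1_override(self, six_record_cohort):
        curves = net_benefit_curves(
            six_record_cohort, np.array([0.3]), p0=0.5, p1=0.2
        )
        c = confusion_at_threshold(six_record_cohort, 0.3)
        assert curves.nb0[0] == pytest.approx(c.tp / 6 - c.tn / 6 * 1.0)
        assert curves.nb1[0] == pytest.approx(c.fp / 6 - c.fn / 6 * 0.25)

    def test_default_grid_includes_observed_scores(self, six_record_cohort):
        grid = default_nb_grid(six_record_cohort)
        assert np.isin(six_record_cohort.scores, grid).all()
        assert grid[-1] <= 1 - 1e-3 + 1e-12

    @pytest.mark.parametrize("bad_grid", [[0.2, 0.9999], [0.5, 0.4], [-0.1, 0.5]])
    def test_invalid_grids_rejected(self, six_record_cohort, bad_grid):
        with pytest.raises(ValueError):
            net_benefit_curves(six_record_cohort, np.array(bad_grid))

    def test_balanced_resample_crossing_sits_at_half(self):
        """With exactly balanced classes the NB difference factors through
        (1 - w), pinning the crossing to t = 0.5."""
        rng = np.random.default_rng(21)
        spec = preset_service_profiles()[1]
        cohort = generate_cohort(spec)
        grid = np.linspace(0.2, 0.8, 601)  # region where J is solidly positive
        curves = net_benefit_curves(cohort, grid, balance=True, rng=rng)
        sel = nb_intersection_threshold(cohort, curves)
        assert sel.threshold == pytest.approx(0.5, abs=0.02)


class TestNbIntersection:
    def test_imbalanced_cohort_starts_with_nb1_above(self, tail_cohort):
        curves = net_benefit_curves(tail_cohort)
        d0 = curves.difference()[0]
        assert d0 == pytest.approx(2 * tail_cohort.prevalence - 1)
        assert d0 < 0

    def test_root_is_bracketed_and_small_residual(self, tail_cohort):
        with pytest.warns(MultipleIntersectionsWarning):
            sel = nb_intersection_threshold(tail_cohort)
        curves = net_benefit_curves(tail_cohort)
        grid, d = curves.grid, curves.difference()
        i = np.searchsorted(grid, sel.threshold) - 1
        assert d[i] * d[i + 1] <= 0  # sign change brackets the root
        residual = np.interp(sel.threshold, grid, d)
        assert abs(residual) <= abs(d[i + 1] - d[i])
        assert sel.crossings[0] == sel.threshold
        assert sel.criterion_value == pytest.approx(
            np.interp(sel.threshold, grid, curves.nb0)
        )

    def test_no_intersection_error_for_centered_low_prevalence(self):
        """Centered score distributions at screening prevalence never cross:
        the error explains itself rather than returning a bogus threshold."""
        spec = preset_service_profiles()[0]
        cohort = generate_cohort(
            type(spec)(
                n=20_000,
                prevalence=0.029,
                score_model=spec.score_model,
                params=spec.params,
                seed=5,
            )
        )
        with pytest.raises(NoIntersectionError, match="do not cross"):
            nb_intersection_threshold(cohort)

    def test_specificity_floor_at_any_low_prevalence_crossing(self):
        """Structural geometry: at a crossing, FP + w*TN = TP + w*FN bounds
        the false positives by the rare-class size, so specificity at any
        intersection of an imbalanced cohort is at least about
        1 - prev/(1-prev)*(1+w)."""
        for seed in range(5):
            cohort = generate_cohort(tail_concentrated_spec(seed=100 + seed))
            with pytest.warns(MultipleIntersectionsWarning):
                sel = nb_intersection_threshold(cohort)
            w = sel.threshold / (1 - sel.threshold)
            prev = cohort.prevalence
            floor = 1 - prev / (1 - prev) * (1 + w)
            assert sel.metrics.sp >= floor - 1e-9
            assert sel.metrics.sp >= 0.95

    def test_grid_too_small_rejected(self, tail_cohort):
        curves = net_benefit_curves(tail_cohort, np.array([0.1, 0.2]))
        with pytest.raises(ValueError, match="at least 3"):
            nb_intersection_threshold(tail_cohort, curves)
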