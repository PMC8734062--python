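"""Closed-form predictive values, posteriors and crossover prevalence.

Expected values come from independent oracles: expected 2x2 cell counts
in a notional cohort, chained single-step Bayes updates, exhaustive
enumeration of joint outcome probabilities, and numeric root-finding.
"""

import math
from itertools import product

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bayescreen import (
    ConvergenceClass,
    InfiniteLikelihoodRatioError,
    TestCharacteristics,
    UndefinedResultError,
    convergence_class,
    intersection_prevalence,
    npv,
    positive_likelihood_ratio,
    posterior_after_sequence,
    ppv,
    sequential_ppv,
)

prob_open = st.floats(0.01, 0.99)


def chained_update(a: float, b: float, phi: float, n: int) -> float:
    """Oracle: feed each posterior back in as the next prior."""
    p = phi
    for _ in range(n):
        p = a * p / (a * p + (1 - b) * (1 - p))
    return p


def enumeration_posterior(a, b, phi, n_pos, n_neg):
    """Oracle: P(D | sequence) by direct joint probabilities."""
    p_seq_d = a**n_pos * (1 - a) ** n_neg * phi
    p_seq_nd = (1 - b) ** n_pos * b**n_neg * (1 - phi)
    return p_seq_d / (p_seq_d + p_seq_nd)


class TestSingleTestPredictiveValues:
    def test_ppv_from_cohort_counts(self, good_test):
        # cohort of 1000 at 10% prevalence: TP = 90, FP = 180
        assert ppv(good_test, 0.1) == pytest.approx(90 / (90 + 180), abs=1e-12)

    def test_npv_from_cohort_counts(self, good_test):
        # same cohort: TN = 720, FN = 10
        assert npv(good_test, 0.1) == pytest.approx(720 / 730, abs=1e-12)

    @pytest.mark.parametrize("phi,expected_ppv,expected_npv",
                             [(0.0, 0.0, 1.0), (1.0, 1.0, 0.0)])
    def test_boundary_prevalence(self, good_test, phi, expected_ppv, expected_npv):
        assert ppv(good_test, phi) == expected_ppv
        assert npv(good_test, phi) == expected_npv

    def test_ppv_zero_over_zero_raises(self):
        perfect_spec = TestCharacteristics(0.9, 1.0)
        with pytest.raises(UndefinedResultError):
            ppv(perfect_spec, 0.0)

    def test_npv_zero_over_zero_raises(self):
        perfect_sens = TestCharacteristics(1.0, 0.8)
        with pytest.raises(UndefinedResultError):
            npv(perfect_sens, 1.0)

    def test_prevalence_out_of_range_rejected(self, good_test):
        with pytest.raises(ValueError):
            ppv(good_test, 1.2)

    @given(phi1=prob_open, phi2=prob_open)
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_ppv_increasing_npv_decreasing_in_prevalence(self, phi1, phi2):
        test = TestCharacteristics(0.9, 0.8)
        lo, hi = sorted((phi1, phi2))
        if hi - lo > 1e-9:
            assert ppv(test, lo) < ppv(test, hi)
            assert npv(test, lo) > npv(test, hi)


class TestLikelihoodRatio:
    @pytest.mark.parametrize("a,b,expected", [
        (0.9, 0.8, 4.5),
        (0.5, 0.5, 1.0),
        (0.3, 0.3, 3 / 7),
    ])
    def test_ratio_values(self, a, b, expected):
        assert positive_likelihood_ratio(TestCharacteristics(a, b)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_perfect_specificity_is_infinite(self):
        with pytest.raises(InfiniteLikelihoodRatioError):
            positive_likelihood_ratio(TestCharacteristics(0.9, 1.0))

    def test_invalid_characteristics_rejected(self):
        with pytest.raises(ValueError):
            TestCharacteristics(0.0, 0.8)
        with pytest.raises(ValueError):
            TestCharacteristics(0.9, 1.1)


class TestSequentialPpv:
    def test_single_iteration_reduces_to_ppv(self, good_test):
        assert sequential_ppv(good_test, 0.1, 1).posterior == pytest.approx(
            ppv(good_test, 0.1), abs=1e-12
        )

    def test_two_iterations_match_chained_updates(self, good_test):
        expected = chained_update(0.9, 0.8, 0.1, 2)  # = 0.69230...
        result = sequential_ppv(good_test, 0.1, 2)
        assert result.posterior == pytest.approx(expected, abs=1e-12)
        assert result.posterior == pytest.approx(0.0810 / (0.081 + 0.036), abs=1e-10)

    def test_hundred_iterations_converges_to_one(self, good_test):
        assert sequential_ppv(good_test, 0.1, 100).posterior == pytest.approx(
            1.0, abs=1e-10
        )

    def test_no_underflow_at_ten_thousand_iterations(self, perverse_test):
        # a^n and (1-b)^n both underflow to 0 in naive arithmetic here,
        # but the ratio form stays finite and converges to 0 (a + b < 1)
        post = sequential_ppv(perverse_test, 0.1, 10_000).posterior
        assert 0.0 <= post < 1e-8

    def test_invalid_n_rejected(self, good_test):
        with pytest.raises(ValueError):
            sequential_ppv(good_test, 0.1, 0)

    @given(
        a=prob_open, b=prob_open, phi=prob_open, n=st.integers(1, 50)
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_chaining_equivalence(self, a, b, phi, n):
        """n-test closed form == n-fold composition of single-step updates."""
        test = TestCharacteristics(a, b)
        closed = sequential_ppv(test, phi, n).posterior
        assert closed == pytest.approx(chained_update(a, b, phi, n), abs=1e-12)


class TestPosteriorAfterSequence:
    def test_empty_sequence_returns_prior(self, good_test):
        result = posterior_after_sequence(good_test, 0.37, [])
        assert result.posterior == 0.37
        assert result.n_positive == result.n_negative == 0

    def test_all_positive_matches_sequential_form(self, good_test):
        seq = posterior_after_sequence(good_test, 0.1, ["+", "+"])
        assert seq.posterior == pytest.approx(
            sequential_ppv(good_test, 0.1, 2).posterior, abs=1e-12
        )

    def test_mixed_sequence_matches_enumeration(self, good_test):
        expected = enumeration_posterior(0.9, 0.8, 0.1, 1, 1)  # 0.009/0.153
        got = posterior_after_sequence(good_test, 0.1, ["+", "-"])
        assert got.posterior == pytest.approx(expected, abs=1e-12)
        assert got.posterior == pytest.approx(0.009 / (0.009 + 0.144), abs=1e-10)

    def test_degenerate_sequence_raises(self):
        # a = 1 makes a negative result impossible for the diseased, and
        # prior 1 leaves no healthy mass: the sequence has probability 0
        certain = TestCharacteristics(1.0, 0.8)
        with pytest.raises(UndefinedResultError):
            posterior_after_sequence(certain, 1.0, ["-"])

    def test_unknown_outcome_token_rejected(self, good_test):
        with pytest.raises(ValueError):
            posterior_after_sequence(good_test, 0.1, ["maybe"])

    @given(
        a=prob_open, b=prob_open, phi=prob_open,
        outcomes=st.lists(st.sampled_from(["+", "-"]), max_size=12),
        seed=st.randoms(use_true_random=False),
    )
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_order_invariance(self, a, b, phi, outcomes, seed):
        test = TestCharacteristics(a, b)
        shuffled = list(outcomes)
        seed.shuffle(shuffled)
        p1 = posterior_after_sequence(test, phi, outcomes).posterior
        p2 = posterior_after_sequence(test, phi, shuffled).posterior
        assert p1 == pytest.approx(p2, abs=1e-12)


class TestConvergenceClass:
    @pytest.mark.parametrize("a,b,expected", [
        (0.9, 0.8, ConvergenceClass.CONVERGES_TO_ONE),
        (0.5, 0.5, ConvergenceClass.STAYS_AT_PRIOR),
        (0.3, 0.7, ConvergenceClass.STAYS_AT_PRIOR),
        (0.3, 0.3, ConvergenceClass.CONVERGES_TO_ZERO),
    ])
    def test_classification(self, a, b, expected):
        assert convergence_class(TestCharacteristics(a, b)) is expected

    def test_converges_to_zero_is_borne_out_numerically(self, perverse_test):
        # oracle: the posterior at n = 1000 falls below any practical eps
        assert sequential_ppv(perverse_test, 0.5, 1000).posterior < 1e-12

    def test_stays_at_prior_is_exact(self, coin_flip_test):
        for n in (1, 7, 123):
            assert sequential_ppv(coin_flip_test, 0.1, n).posterior == pytest.approx(
                0.1, abs=1e-12
            )


class TestIntersectionPrevalence:
    def root_oracle(self, a, b):
        """Bisection on ppv(phi) - npv(phi) over (0, 1)."""
        from scipy.optimize import brentq

        test = TestCharacteristics(a, b)
        return brentq(
            lambda p: ppv(test, p) - npv(test, p), 1e-12, 1 - 1e-12, xtol=1e-14
        )

    def test_symmetric_test_crosses_at_half(self):
        for a in (0.2, 0.5, 0.8, 0.95):
            assert intersection_prevalence(TestCharacteristics(a, a)) == 0.5

    def test_standard_example(self, good_test):
        phi_i = intersection_prevalence(good_test)
        assert phi_i == pytest.approx(4 / 7, abs=1e-9)
        assert phi_i == pytest.approx(self.root_oracle(0.9, 0.8), abs=1e-9)

    def test_crossing_can_leave_forty_sixty_band(self):
        # a high-sensitivity low-specificity test crosses near 0.83,
        # well outside the 40-60% band typical tests show
        phi_i = intersection_prevalence(TestCharacteristics(0.99, 0.51))
        assert phi_i == pytest.approx(self.root_oracle(0.99, 0.51), abs=1e-9)
        assert phi_i > 0.8

    @pytest.mark.parametrize("a,b", [
        (a, b)
        for a, b in product((0.1, 0.35, 0.6, 0.9), repeat=2)
        if abs(a - b) > 1e-9 and abs(a + b - 1) > 1e-9
    ])
    def test_matches_numeric_root_across_regimes(self, a, b):
        assert intersection_prevalence(TestCharacteristics(a, b)) == pytest.approx(
            self.root_oracle(a, b), abs=1e-9
        )

    def test_boundary_characteristics_rejected(self):
        with pytest.raises(ValueError):
            intersection_prevalence(TestCharacteristics(1.0, 0.8))
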