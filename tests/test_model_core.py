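import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crosswise.model_core import (
    CrosswiseCounts,
    EmptySubsampleError,
    InvalidDesignError,
    RandomizationDesign,
    SelfProtectionParams,
    moment_matrix,
    moment_pooled,
    moment_subsample,
    sp_expected_naive_estimate,
    sp_transition_matrix,
    transition_matrix,
)

probs = st.floats(0.05, 0.95).filter(lambda p: abs(p - 0.5) > 0.02)
cells = st.integers(1, 500)


def make_counts(n21, n11, n22, n12, p1=0.2, label="t"):
    return CrosswiseCounts(label, n21, n11, n22, n12, RandomizationDesign(p1))


class TestMomentSubsample:
    @pytest.mark.parametrize(
        "n2s, ns, ps, expected",
        [
            (249, 361, 0.2, 0.1837488465),  # observed arm of a real study question
            (20, 100, 0.8, 0.0),  # proportion at the all-non-carrier expectation 1-ps
            (100, 100, 0.8, 4.0 / 3.0),  # out-of-range estimates are returned unclipped
        ],
    )
    def test_formula(self, n2s, ns, ps, expected):
        assert moment_subsample(n2s, ns, ps) == pytest.approx(expected, abs=1e-9)

    def test_invalid_design(self):
        with pytest.raises(InvalidDesignError):
            moment_subsample(10, 20, 0.5)

    def test_empty_subsample(self):
        with pytest.raises(EmptySubsampleError):
            moment_subsample(0, 0, 0.2)


class TestMomentPooled:
    def test_drug_use1_q1(self, questions):
        est = moment_pooled(questions["Drug use1-Q1"].counts)
        assert round(100 * est.pi_hat, 1) == 26.2

    def test_truncated_lower_ci(self, questions):
        est = moment_pooled(questions["Drug use2-Q4"].counts)
        assert round(100 * est.pi_hat, 1) == 3.8
        assert est.ci_low == 0.0
        assert round(100 * est.ci_high, 1) == 7.7

    def test_symmetric_counts_give_half(self):
        est = moment_pooled(make_counts(50, 50, 80, 80, p1=0.3))
        assert est.pi_hat == pytest.approx(0.5, abs=1e-12)

    @given(n21=cells, n11=cells, n22=cells, n12=cells, p1=probs)
    def test_relabel_invariance(self, n21, n11, n22, n12, p1):
        """Swapping the arm labels (and complementing p1) leaves the estimate fixed."""
        c = make_counts(n21, n11, n22, n12, p1)
        a, b = moment_pooled(c), moment_pooled(c.relabeled())
        assert a.pi_hat == pytest.approx(b.pi_hat, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, rel=1e-12)

    @given(pi=st.floats(0.01, 0.99), p1=probs, n1=st.integers(50, 400), n2=st.integers(50, 400))
    def test_consistency_on_expected_counts(self, pi, p1, n1, n2):
        """Feeding exact model expected counts recovers pi without error."""
        P = transition_matrix(RandomizationDesign(p1))
        pr = P @ np.array([pi, 1 - pi])
        c = make_counts(n1 * pr[0], n1 * pr[1], n2 * pr[2], n2 * pr[3], p1)
        assert moment_pooled(c).pi_hat == pytest.approx(pi, abs=1e-10)


class TestTransitionMatrix:
    def test_values(self):
        P = transition_matrix(RandomizationDesign(0.8))
        expected = np.array([[0.8, 0.2], [0.2, 0.8], [0.2, 0.8], [0.8, 0.2]])
        np.testing.assert_allclose(P, expected)

    def test_degenerate_control_design(self):
        P = transition_matrix(RandomizationDesign(1.0))
        np.testing.assert_allclose(P, [[1, 0], [0, 1], [0, 1], [1, 0]])

    @given(p1=probs, pi=st.floats(0, 1))
    def test_normalization_and_symmetry(self, p1, pi):
        P = transition_matrix(RandomizationDesign(p1))
        pr = P @ np.array([pi, 1 - pi])
        # each sub-sample's response probabilities sum to one
        assert pr[0] + pr[1] == pytest.approx(1.0, abs=1e-12)
        assert pr[2] + pr[3] == pytest.approx(1.0, abs=1e-12)
        # cross-arm symmetry underlying the identifiability argument
        assert pr[0] == pytest.approx(pr[3], abs=1e-12)
        assert pr[1] == pytest.approx(pr[2], abs=1e-12)


class TestMomentMatrix:
    @given(n21=cells, n11=cells, n22=cells, n12=cells, p1=probs)
    def test_equals_pooled_when_balanced(self, n21, n11, n22, n12, p1):
        n1 = n21 + n11
        if n1 - n22 < 0:
            return
        c = make_counts(n21, n11, n22, n1 - n22, p1)  # force n1 == n2
        a, b = moment_matrix(c), moment_pooled(c)
        assert a.pi_hat == pytest.approx(b.pi_hat, abs=1e-10)

    def test_covid_f1(self, questions):
        est = moment_matrix(questions["Covid-F1"].counts)
        assert est.pi_hat == pytest.approx(0.334, abs=0.01)

    def test_consistency_on_model_manifold(self):
        pi, p1, n1, n2 = 0.3, 0.8, 200, 200
        P = transition_matrix(RandomizationDesign(p1))
        pr = P @ np.array([pi, 1 - pi])
        c = make_counts(n1 * pr[0], n1 * pr[1], n2 * pr[2], n2 * pr[3], p1)
        assert moment_matrix(c).pi_hat == pytest.approx(pi, abs=1e-10)


class TestSelfProtection:
    def test_zero_theta_recovers_clean_matrix(self):
        d = RandomizationDesign(0.8)
        np.testing.assert_allclose(
            sp_transition_matrix(d, SelfProtectionParams(0, 0)), transition_matrix(d)
        )

    def test_implied_response_probabilities(self):
        Q = sp_transition_matrix(RandomizationDesign(0.8), SelfProtectionParams(0.5, 0.0))
        pr = Q @ np.array([0.3, 0.7])
        np.testing.assert_allclose(pr, [0.26, 0.74, 0.74, 0.26], atol=1e-12)

    @given(p1=st.floats(0.55, 0.99), tc=st.floats(0, 1), tnc=st.floats(0, 1))
    def test_row_symmetry_and_column_stochastic(self, p1, tc, tnc):
        Q = sp_transition_matrix(RandomizationDesign(p1), SelfProtectionParams(tc, tnc))
        np.testing.assert_allclose(Q[0], Q[3])
        np.testing.assert_allclose(Q[1], Q[2])
        np.testing.assert_allclose(Q[:2].sum(axis=0), [1, 1])

    def test_requires_p1_above_half(self):
        with pytest.raises(InvalidDesignError):
            sp_transition_matrix(RandomizationDesign(0.2), SelfProtectionParams(0.1, 0))

    @pytest.mark.parametrize(
        "pi, tc, tnc, expected",
        [
            (0.3, 0.5, 0.0, 0.1),
            (0.3, 0.0, 0.0, 0.3),  # unbiased without contamination
            (0.4, 1.0, 0.0, -0.4 / 3.0),  # full carrier self-protection: negative limit
        ],
    )
    def test_expected_naive_estimate(self, pi, tc, tnc, expected):
        val = sp_expected_naive_estimate(
            pi, RandomizationDesign(0.8), SelfProtectionParams(tc, tnc)
        )
        assert val == pytest.approx(expected, abs=1e-12)

    @given(
        pi=st.floats(0, 1),
        p1=st.floats(0.55, 0.95),
        tc=st.floats(0, 1),
        tnc=st.floats(0, 1),
    )
    def test_matches_closed_form_and_both_arms(self, pi, p1, tc, tnc):
        """The Q-then-invert construction agrees with the algebraic bias
        formula, and both arms imply the same probability limit."""
        d = RandomizationDesign(p1)
        th = SelfProtectionParams(tc, tnc)
        val = sp_expected_naive_estimate(pi, d, th)
        closed = (
            pi * (p1 * (1 - tc) - (1 - p1)) - tnc * (1 - p1) * (1 - pi)
        ) / (2 * p1 - 1)
        assert val == pytest.approx(closed, abs=1e-10)
        pr = sp_transition_matrix(d, th) @ np.array([pi, 1 - pi])
        arm2 = moment_subsample(pr[2], 1.0, d.p2)
        assert val == pytest.approx(arm2, abs=1e-10)
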