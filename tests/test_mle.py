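import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.special import expit

from crosswise.mle import fit, gof_test, interior_mle, loglik, prevalence_from_fit, response_prob
from crosswise.model_core import (
    CrosswiseCounts,
    RandomizationDesign,
    moment_pooled,
    moment_subsample,
    transition_matrix,
)

cells = st.integers(1, 500)
probs = st.floats(0.05, 0.95).filter(lambda p: abs(p - 0.5) > 0.02)


def make_counts(n21, n11, n22, n12, p1=0.2, label="t"):
    return CrosswiseCounts(label, n21, n11, n22, n12, RandomizationDesign(p1))


def expand(counts):
    """Respondent-level table equivalent to an aggregated count table."""
    rows = []
    for (y, s), k in zip(
        [(2, 1), (1, 1), (2, 2), (1, 2)], counts.as_vector().astype(int)
    ):
        rows += [{"y": y, "s": s}] * k
    return pd.DataFrame(rows)


class TestResponseProb:
    @pytest.mark.parametrize(
        "y, s, pi, expected",
        [
            (2, 1, 0.0, 0.2),  # non-carrier mismatch probability
            (2, 1, 0.3, 0.38),
            (1, 2, 0.3, 0.38),  # cross-arm symmetry
            (2, 2, 0.5, 0.5),
        ],
    )
    def test_values(self, y, s, pi, expected):
        d = RandomizationDesign(0.8)
        assert response_prob(y, s, pi, d) == pytest.approx(expected, abs=1e-12)

    def test_invalid_codes(self):
        d = RandomizationDesign(0.8)
        with pytest.raises(ValueError):
            response_prob(3, 1, 0.2, d)
        with pytest.raises(ValueError):
            response_prob(1, 0, 0.2, d)


class TestLoglik:
    def test_beta_zero_gives_n_log_half(self, questions):
        c = questions["Drug use1-Q1"].counts
        assert loglik([0.0], c) == pytest.approx(c.n * math.log(0.5), rel=1e-12)

    def test_counts_equal_expanded_records(self, questions):
        c = questions["Covid-F2"].counts
        beta = [0.4]
        ll_records = loglik(beta, expand(c), design=c.design)
        assert loglik(beta, c) == pytest.approx(ll_records, rel=1e-12)

    def test_loglik_at_mle_is_multinomial(self, questions):
        """At the optimum the likelihood equals the multinomial evaluated
        at the fitted cell probabilities."""
        c = questions["Drug use1-Q1"].counts
        f = fit(c)
        pi = expit(f.beta[0])
        P = transition_matrix(c.design)
        pr = P @ np.array([pi, 1 - pi])
        expected = float(np.sum(c.as_vector() * np.log(pr)))
        assert f.loglik == pytest.approx(expected, rel=1e-10)


class TestFit:
    def test_intercept_only_matches_pooled_moment(self, questions):
        """Interior ML and pooled moment point estimates are identical."""
        for q in questions.values():
            mom = moment_pooled(q.counts)
            mle_pi = expit(fit(q.counts).beta[0])
            assert mle_pi == pytest.approx(mom.pi_hat, abs=1e-6), q.label

    def test_subsample_covariate_recovers_per_arm_moments(self, questions):
        c = questions["Drug use1-Q1"].counts
        f = fit(c, covariates="subsample")
        pi1 = expit(f.beta[0])
        pi2 = expit(f.beta[0] + f.beta[1])
        assert pi1 == pytest.approx(moment_subsample(c.n21, c.n1, c.design.p1), abs=1e-6)
        assert pi2 == pytest.approx(moment_subsample(c.n22, c.n2, c.design.p2), abs=1e-6)

    def test_fit_on_records_equals_fit_on_counts(self, questions):
        c = questions["Covid-J3"].counts
        f1 = fit(c)
        f2 = fit(expand(c), design=c.design)
        assert f1.beta[0] == pytest.approx(f2.beta[0], abs=1e-6)
        assert f1.loglik == pytest.approx(f2.loglik, rel=1e-10)

    def test_boundary_detection(self):
        c = make_counts(10, 90, 85, 15, p1=0.8)  # pooled moment estimate below zero
        f = fit(c)
        assert f.boundary
        est = prevalence_from_fit(f)
        assert est.pi_hat == 0.0
        assert est.boundary


class TestPrevalenceFromFit:
    def test_covid_f1_interval(self, questions):
        est = prevalence_from_fit(fit(questions["Covid-F1"].counts))
        assert round(100 * est.pi_hat, 1) == 33.4
        assert est.ci_low == pytest.approx(0.278, abs=2e-3)
        assert est.ci_high == pytest.approx(0.389, abs=2e-3)

    def test_delta_se_close_to_moment_variance(self):
        """On balanced interior data the delta-method SE agrees with the
        closed-form pooled variance within 2%."""
        pi, p1, n = 0.3, 0.8, 500
        P = transition_matrix(RandomizationDesign(p1))
        pr = P @ np.array([pi, 1 - pi])
        c = make_counts(n * pr[0], n * pr[1], n * pr[2], n * pr[3], p1)
        est_mle = prevalence_from_fit(fit(c))
        est_mom = moment_pooled(c)
        assert est_mle.se == pytest.approx(est_mom.se, rel=0.02)

    def test_zero_logit_with_zero_se(self):
        f = fit(make_counts(50, 50, 50, 50, p1=0.8))
        est = prevalence_from_fit(f)
        assert est.pi_hat == pytest.approx(0.5, abs=1e-8)


class TestGof:
    @pytest.mark.parametrize(
        "label, g2, p",
        [("Drug use1-Q1", 6.77, 0.009), ("Drug use2-Q1", 16.46, 0.000)],
    )
    def test_reference_values(self, questions, label, g2, p):
        r = gof_test(questions[label].counts)
        assert r.g2_stat == pytest.approx(g2, abs=0.005)
        assert round(r.p_value, 3) == p

    def test_zero_on_model_manifold(self):
        pi, p1 = 0.3, 0.8
        P = transition_matrix(RandomizationDesign(p1))
        pr = P @ np.array([pi, 1 - pi])
        c = make_counts(300 * pr[0], 300 * pr[1], 200 * pr[2], 200 * pr[3], p1)
        r = gof_test(c)
        assert r.lr_stat == pytest.approx(0.0, abs=1e-10)
        assert r.g2_stat == pytest.approx(0.0, abs=1e-10)

    def test_lr_equals_g2_when_interior(self, questions):
        for q in questions.values():
            r = gof_test(q.counts)
            assert not r.boundary
            assert r.lr_stat == pytest.approx(r.g2_stat, abs=1e-6), q.label

    def test_lr_equals_covariate_likelihood_ratio(self, questions):
        """The closed-form statistic equals twice the log-likelihood gap of
        the fits with and without the sub-sample covariate."""
        c = questions["Drug use1-Q4"].counts
        lr = 2 * (fit(c, covariates="subsample").loglik - fit(c).loglik)
        assert gof_test(c).lr_stat == pytest.approx(lr, abs=1e-6)

    def test_boundary_gives_zero_lr_positive_g2(self):
        c = make_counts(10, 90, 85, 15, p1=0.8)
        r = gof_test(c)
        assert r.boundary
        assert r.lr_stat == 0.0
        assert r.g2_stat > 0.0

    @given(n21=cells, n11=cells, n22=cells, n12=cells, p1=probs)
    def test_invariances_and_ordering(self, n21, n11, n22, n12, p1):
        c = make_counts(n21, n11, n22, n12, p1)
        r = gof_test(c)
        assert r.lr_stat >= 0  # saturated model never fits worse
        rf = gof_test(c.relabeled())
        assert r.lr_stat == pytest.approx(rf.lr_stat, abs=1e-8)
        assert r.g2_stat == pytest.approx(rf.g2_stat, abs=1e-8)
        assert interior_mle(c) == pytest.approx(interior_mle(c.relabeled()), abs=1e-12)
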