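"""Domain types and closed-form (moment) estimation for the extended crosswise model.

The extended crosswise model (ECWM) is a randomized response design for
asking sensitive yes/no questions.  Each respondent jointly answers the
sensitive question and an innocuous *unrelated* question whose "Yes"
probability is fixed by design, and reports only whether the two answers
match ("TWO 'Yes' or TWO 'No'", coded ``y = 2``) or not ("ONE 'Yes'",
coded ``y = 1``).  The sample is split into two sub-samples with
complementary unrelated-question probabilities ``p1`` and ``p2 = 1 - p1``,
which buys one degree of freedom for a goodness-of-fit test while keeping
both response options non-incriminating.

This module provides the design and count containers, the per-sub-sample
and pooled moment estimators of the prevalence pi, the 4x2 transition
matrix linking prevalence to response probabilities, a generalized-inverse
matrix estimator, and the transition matrix under *informed
self-protection* (respondents who know which response is incriminating in
their arm and deliberately emit the safe one).  The self-protection model
is not identified -- contaminated data remain perfectly consistent with
the clean model -- and the algebra here makes the resulting bias explicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Z95",
    "InvalidDesignError",
    "EmptySubsampleError",
    "RandomizationDesign",
    "CrosswiseCounts",
    "PrevalenceEstimate",
    "SelfProtectionParams",
    "moment_subsample",
    "moment_pooled",
    "pooled_variance",
    "transition_matrix",
    "moment_matrix",
    "sp_transition_matrix",
    "sp_expected_naive_estimate",
]

#: Two-sided 95% standard-normal quantile, at the precision conventionally used.
Z95 = 1.959964


class InvalidDesignError(ValueError):
    """Raised for randomization designs under which pi is not estimable."""


class EmptySubsampleError(ValueError):
    """Raised when a sub-sample contains no observations."""


@dataclass(frozen=True)
class RandomizationDesign:
    """Pair of complementary unrelated-question "Yes" probabilities.

    Parameters
    ----------
    p1 : float
        Probability of a "Yes" answer to the unrelated question in
        sub-sample 1.  Sub-sample 2 uses ``p2 = 1 - p1`` exactly.
        ``p1 = 0.5`` is not a valid design: the estimators divide by
        ``2*p1 - 1``.  The degenerate values 0 and 1 are admissible only
        for control items with known prevalence.
    """

    p1: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p1 <= 1.0:
            raise InvalidDesignError(f"p1 must be in [0, 1], got {self.p1}")
        if self.p1 == 0.5:
            raise InvalidDesignError(
                "p1 = 0.5 makes the prevalence unidentifiable (division by 2*p1 - 1)"
            )

    @property
    def p2(self) -> float:
        return 1.0 - self.p1

    def p(self, s: int) -> float:
        """Unrelated-question "Yes" probability in sub-sample ``s`` (1 or 2)."""
        if s == 1:
            return self.p1
        if s == 2:
            return self.p2
        raise ValueError(f"sub-sample must be 1 or 2, got {s}")


@dataclass(frozen=True)
class CrosswiseCounts:
    """Observed 2x2 ECWM response table for one question.

    ``n_ys`` is the count of response ``y`` in sub-sample ``s``; response 2
    is "TWO 'Yes' or TWO 'No'", response 1 is "ONE 'Yes'".  Counts are
    usually integers but floats are accepted so that expected-count tables
    (model probabilities scaled by sample size) can flow through the same
    estimation code.
    """

    label: str
    n21: float
    n11: float
    n22: float
    n12: float
    design: RandomizationDesign = field(default_factory=lambda: RandomizationDesign(0.2))

    def __post_init__(self) -> None:
        for name in ("n21", "n11", "n22", "n12"):
            v = getattr(self, name)
            if v < 0 or not math.isfinite(v):
                raise ValueError(f"{name} must be a finite nonnegative count, got {v}")

    @property
    def n1(self) -> float:
        return self.n21 + self.n11

    @property
    def n2(self) -> float:
        return self.n22 + self.n12

    @property
    def n(self) -> float:
        return self.n1 + self.n2

    def as_vector(self) -> np.ndarray:
        """Counts in the canonical row order (2|1, 1|1, 2|2, 1|2)."""
        return np.array([self.n21, self.n11, self.n22, self.n12], dtype=float)

    def relabeled(self) -> "CrosswiseCounts":
        """Swap the sub-sample labels and complement p1 accordingly.

        Which arm is called "1" is presentational; every estimator in the
        package is invariant under this relabeling."""
        return CrosswiseCounts(
            label=self.label,
            n21=self.n22,
            n11=self.n12,
            n22=self.n21,
            n12=self.n11,
            design=RandomizationDesign(self.design.p2),
        )


@dataclass(frozen=True)
class PrevalenceEstimate:
    """Point estimate of a prevalence with its Wald uncertainty.

    ``pi_hat`` may fall outside [0, 1] for the moment estimators (a
    documented feature of randomized-response moment estimation, useful
    as a diagnostic); confidence limits are always truncated to [0, 1].
    """

    pi_hat: float
    variance: float
    ci_low: float
    ci_high: float
    method: str
    boundary: bool = False

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be nonnegative")
        if not (0.0 <= self.ci_low <= self.ci_high <= 1.0):
            raise ValueError("confidence limits must satisfy 0 <= low <= high <= 1")

    @property
    def se(self) -> float:
        return math.sqrt(self.variance)


@dataclass(frozen=True)
class SelfProtectionParams:
    """Rates of informed self-protective answering.

    ``theta_c`` is the probability that a carrier of the sensitive
    attribute deliberately emits the safe response for their arm;
    ``theta_nc`` the same for non-carriers.
    """

    theta_c: float = 0.0
    theta_nc: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.theta_c <= 1.0 and 0.0 <= self.theta_nc <= 1.0):
            raise ValueError("self-protection rates must lie in [0, 1]")


def _wald_ci(pi_hat: float, variance: float) -> tuple[float, float]:
    half = Z95 * math.sqrt(variance)
    return (min(max(pi_hat - half, 0.0), 1.0), min(max(pi_hat + half, 0.0), 1.0))


def moment_subsample(n2s: float, ns: float, ps: float) -> float:
    """Per-sub-sample moment estimator of the prevalence.

    Inverts the model probability P(y=2 | s) = ps*pi + (1-ps)*(1-pi):

        pi_hat_s = (n2s/ns - 1 + ps) / (2*ps - 1)

    The result is returned unclipped: it is negative whenever the observed
    proportion of matching answers falls on the wrong side of ``1 - ps``,
    and can exceed 1 symmetrically.
    """
    if ns <= 0:
        raise EmptySubsampleError("sub-sample contains no observations")
    if ps == 0.5:
        raise InvalidDesignError("ps = 0.5 is not an admissible randomization probability")
    return (n2s / ns - 1.0 + ps) / (2.0 * ps - 1.0)


def pooled_variance(pi: float, n: float, p1: float) -> float:
    """Variance of the pooled moment estimator.

        V(pi_hat) = [pi*(1 - pi) + p1*(1 - p1)/(2*p1 - 1)^2] / n

    identical to the crosswise-model variance.  ``pi`` is clipped to
    [0, 1] inside the binomial term so that out-of-range moment estimates
    cannot produce a negative variance.
    """
    if p1 == 0.5:
        raise InvalidDesignError("p1 = 0.5 has infinite estimator variance")
    pc = min(max(pi, 0.0), 1.0)
    return (pc * (1.0 - pc) + p1 * (1.0 - p1) / (2.0 * p1 - 1.0) ** 2) / n


def moment_pooled(counts: CrosswiseCounts) -> PrevalenceEstimate:
    """Pooled moment estimator: sub-sample-size weighted average of the
    two per-sub-sample moment estimates, with the crosswise variance.

    For interior solutions this coincides exactly with the intercept-only
    maximum-likelihood estimate.
    """
    d = counts.design
    if counts.n1 <= 0 or counts.n2 <= 0:
        raise EmptySubsampleError(f"{counts.label}: both sub-samples must be nonempty")
    pi1 = moment_subsample(counts.n21, counts.n1, d.p1)
    pi2 = moment_subsample(counts.n22, counts.n2, d.p2)
    pi = (counts.n1 * pi1 + counts.n2 * pi2) / counts.n
    var = pooled_variance(pi, counts.n, d.p1)
    lo, hi = _wald_ci(pi, var)
    return PrevalenceEstimate(pi, var, lo, hi, method="moment_weighted")


def transition_matrix(design: RandomizationDesign) -> np.ndarray:
    """4x2 transition matrix P mapping (pi, 1-pi)' to the conditional
    response probabilities in row order (2|1, 1|1, 2|2, 1|2); columns are
    (carrier, non-carrier).  Rows 1 and 4 coincide, as do rows 2 and 3 --
    the symmetry that makes informed self-protection undetectable.
    """
    p1 = design.p1
    return np.array(
        [
            [p1, 1.0 - p1],
            [1.0 - p1, p1],
            [1.0 - p1, p1],
            [p1, 1.0 - p1],
        ]
    )


def moment_matrix(counts: CrosswiseCounts) -> PrevalenceEstimate:
    """Generalized-inverse moment estimator.

    Estimates pi in one step as the first element of ``2 * pinv(P) @ f``
    where ``f`` holds the unconditional response proportions ``n_ys / n``.
    The variance is the (1,1) element of the corresponding sandwich form

        4/n * pinv(P) (diag(f) - f f') pinv(P)'.

    With balanced sub-samples this reduces exactly to :func:`moment_pooled`.
    """
    d = counts.design
    if counts.n <= 0:
        raise EmptySubsampleError(f"{counts.label}: no observations")
    if d.p1 == 0.5:
        raise InvalidDesignError("p1 = 0.5 is not an admissible design")
    P = transition_matrix(d)
    f = counts.as_vector() / counts.n
    Pinv = np.linalg.pinv(P)
    pi = float(2.0 * (Pinv @ f)[0])
    cov = 4.0 / counts.n * Pinv @ (np.diag(f) - np.outer(f, f)) @ Pinv.T
    var = float(cov[0, 0])
    lo, hi = _wald_ci(pi, var)
    return PrevalenceEstimate(pi, max(var, 0.0), lo, hi, method="moment_matrix")


def sp_transition_matrix(
    design: RandomizationDesign, theta: SelfProtectionParams
) -> np.ndarray:
    """Transition matrix Q under informed self-protection.

    Convention: ``p1 > p2``, so the incriminating response is ``y = 2`` in
    sub-sample 1 and ``y = 1`` in sub-sample 2.  Carriers divert from the
    incriminating response with probability ``theta_c``, non-carriers with
    ``theta_nc``.  Column-stochasticity per sub-sample fixes the
    complementary rows:

        rows 1, 4: ( p1*(1-theta_c),      (1-theta_nc)*(1-p1) )
        rows 2, 3: ( 1 - p1*(1-theta_c),  p1 + theta_nc*(1-p1) )

    With ``theta_c = theta_nc = 0`` this is exactly
    :func:`transition_matrix`.  Q preserves the row equalities 1=4 and
    2=3 of P, which is why self-protected data still fit the clean model
    perfectly and the theta parameters are unidentified.
    """
    if design.p1 <= 0.5:
        raise InvalidDesignError(
            "self-protection convention requires p1 > p2, i.e. p1 > 0.5"
        )
    p1, tc, tnc = design.p1, theta.theta_c, theta.theta_nc
    row_a = [p1 * (1.0 - tc), (1.0 - tnc) * (1.0 - p1)]
    row_b = [1.0 - p1 * (1.0 - tc), p1 + tnc * (1.0 - p1)]
    return np.array([row_a, row_b, row_b, row_a])


def sp_expected_naive_estimate(
    pi: float, design: RandomizationDesign, theta: SelfProtectionParams
) -> float:
    """Probability limit of the naive moment estimator under informed
    self-protection: apply the sub-sample-1 moment inversion to the
    response probabilities implied by Q.  Both sub-samples give the same
    value by the row symmetry of Q.

    For ``theta_nc = 0`` this reduces to the closed form
    ``pi * (1 - p1*theta_c / (2*p1 - 1))``; it can be negative.
    """
    Q = sp_transition_matrix(design, theta)
    probs = Q @ np.array([pi, 1.0 - pi])
    return moment_subsample(probs[0], 1.0, design.p1)
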