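"""Direct-question estimation and comparisons between survey conditions.

Direct questioning (DQ) is the conventional yes/no self-report used as the
benchmark condition.  Under the "more-is-better" criterion, a
privacy-protecting design should recover *higher* prevalence estimates
than DQ for socially undesirable attributes (less underreporting) and
equal estimates for non-sensitive ones.  This module provides the
binomial DQ estimator, two-sample z comparisons between an ECWM estimate
and a DQ estimate (or between two ECWM conditions), and the Pearson
chi-square used to compare control-question error rates across studies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from scipy.stats import chi2_contingency, norm

from .model_core import Z95, PrevalenceEstimate

__all__ = [
    "DirectCounts",
    "ComparisonResult",
    "dq_estimate",
    "compare_ecwm_dq",
    "compare_two_ecwm",
    "error_rate_chi2",
]


@dataclass(frozen=True)
class DirectCounts:
    """Yes/no counts from a direct-question condition."""

    n_yes: int
    n_no: int

    def __post_init__(self) -> None:
        if self.n_yes < 0 or self.n_no < 0:
            raise ValueError("counts must be nonnegative")

    @property
    def n(self) -> int:
        return self.n_yes + self.n_no


@dataclass(frozen=True)
class ComparisonResult:
    """Two-sample comparison of prevalence estimates.

    ``delta`` is on the proportion scale; ``statistic`` carries the
    chi-square value for :func:`error_rate_chi2` (where ``z ** 2 ==
    statistic``) and is None for plain z comparisons.
    """

    delta: float
    se_delta: float
    z: float
    p_value: float
    two_sided: bool = True
    statistic: float | None = None


def dq_estimate(counts: DirectCounts) -> PrevalenceEstimate:
    """Binomial proportion estimate with Wald variance and 95% CI."""
    if counts.n <= 0:
        raise ValueError("direct-question condition has no observations")
    pi = counts.n_yes / counts.n
    var = pi * (1.0 - pi) / counts.n
    half = Z95 * math.sqrt(var)
    lo = min(max(pi - half, 0.0), 1.0)
    hi = min(max(pi + half, 0.0), 1.0)
    return PrevalenceEstimate(pi, var, lo, hi, method="dq_wald")


def _z_compare(e1: PrevalenceEstimate, e2: PrevalenceEstimate) -> ComparisonResult:
    delta = e1.pi_hat - e2.pi_hat
    se = math.sqrt(e1.variance + e2.variance)
    if se == 0.0:
        z = 0.0 if delta == 0.0 else math.copysign(math.inf, delta)
    else:
        z = delta / se
    p = 2.0 * float(norm.sf(abs(z)))
    return ComparisonResult(delta=delta, se_delta=se, z=z, p_value=p)


def compare_ecwm_dq(ecwm: PrevalenceEstimate, dq: PrevalenceEstimate) -> ComparisonResult:
    """z test of the ECWM-minus-DQ prevalence difference.

    ``z = delta / sqrt(V_ecwm + V_dq)`` with each estimate's own variance;
    positive values support the more-is-better criterion.
    """
    return _z_compare(ecwm, dq)


def compare_two_ecwm(e1: PrevalenceEstimate, e2: PrevalenceEstimate) -> ComparisonResult:
    """z test of the difference between two independent ECWM estimates
    (e.g. question vs statement wording of the same item)."""
    return _z_compare(e1, e2)


def error_rate_chi2(k1: int, n1: int, k2: int, n2: int) -> ComparisonResult:
    """Pearson chi-square (1 df, no continuity correction) comparing two
    error rates ``k1/n1`` and ``k2/n2`` on a control question.

    The statistic equals the squared two-proportion z statistic; the
    signed z is also returned.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    table = [[k1, n1 - k1], [k2, n2 - k2]]
    if min(k1 + k2, (n1 - k1) + (n2 - k2)) == 0:
        raise ValueError("degenerate margin: chi-square statistic undefined")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    r1, r2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (r1 - r2) / se if se > 0 else 0.0
    return ComparisonResult(
        delta=r1 - r2, se_delta=se, z=z, p_value=float(p), statistic=float(stat)
    )
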