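"""Maximum-likelihood estimation, logistic regression, and goodness of fit
for the extended crosswise model.

The observation model for respondent ``i`` in sub-sample ``s`` is

    P(y_i = 2) = p_s * pi_i + (1 - p_s) * (1 - pi_i)
    P(y_i = 1) = 1 - P(y_i = 2)

with the individual prevalence linked to covariates through a logit,
``pi_i = expit(x_i' beta)``.  The intercept-only fit gives the population
prevalence; adding a sub-sample-membership indicator saturates the model
(one fitted prevalence per arm) and twice the log-likelihood difference is
the 1-df goodness-of-fit statistic, identical to the G^2 discrepancy
``2 * sum n_ys log(n_ys / fitted_ys)`` whenever the null estimate is
interior.  At a boundary solution (prevalence 0 or 1) the likelihood-ratio
statistic collapses to zero while G^2 stays positive, and the two are
reported separately.

For the intercept-only model the score equation is linear in pi, so the
constrained maximizer over [0, 1] has a closed form (the pooled moment
estimate, clipped); the goodness-of-fit test exploits this and needs no
iterative optimization.  Regression fits with arbitrary covariates go
through BFGS on the unconstrained logit scale with an analytic gradient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit
from scipy.stats import chi2

from .model_core import (
    Z95,
    CrosswiseCounts,
    EmptySubsampleError,
    PrevalenceEstimate,
    RandomizationDesign,
    pooled_variance,
)

__all__ = [
    "EcwmFit",
    "GofResult",
    "ConvergenceError",
    "response_prob",
    "loglik",
    "fit",
    "prevalence_from_fit",
    "gof_test",
    "interior_mle",
]

#: Back-transformed prevalence within this distance of 0 or 1 is a boundary solution.
BOUNDARY_TOL = 1e-6


class ConvergenceError(RuntimeError):
    """Optimizer failed to converge; carries the scipy result for diagnosis."""

    def __init__(self, message: str, result: object) -> None:
        super().__init__(message)
        self.result = result


@dataclass(frozen=True)
class EcwmFit:
    """Fitted ECWM logistic model.

    ``beta`` is on the logit scale with the intercept first; ``vcov`` is
    the inverse observed information (numerically differenced Hessian).
    ``boundary`` marks intercept-only fits whose prevalence estimate is
    pinned at 0 or 1, where the Hessian-based variance is unavailable.
    """

    beta: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    n_obs: float
    design: RandomizationDesign
    columns: tuple[str, ...]


@dataclass(frozen=True)
class GofResult:
    """1-df goodness-of-fit test of the ECWM for one question.

    ``lr_stat`` is the likelihood-ratio statistic (null = intercept-only,
    alternative = per-sub-sample prevalences); ``g2_stat`` is the
    discrepancy ``2 sum n log(n / fitted)`` against the observed table.
    They coincide unless the null solution is on the boundary, in which
    case ``lr_stat`` is 0 while ``g2_stat`` remains positive.
    """

    lr_stat: float
    g2_stat: float
    df: int
    p_value: float
    boundary: bool


def response_prob(y, s, pi_i, design: RandomizationDesign):
    """Model probability of response ``y`` in sub-sample ``s`` given the
    individual prevalence ``pi_i``.  Vectorized over all arguments."""
    y = np.asarray(y)
    s = np.asarray(s)
    pi_i = np.asarray(pi_i, dtype=float)
    if not np.all((y == 1) | (y == 2)):
        raise ValueError("responses must be coded 1 or 2")
    if not np.all((s == 1) | (s == 2)):
        raise ValueError("sub-samples must be coded 1 or 2")
    ps = np.where(s == 1, design.p1, design.p2)
    p2 = ps * pi_i + (1.0 - ps) * (1.0 - pi_i)
    out = np.where(y == 2, p2, 1.0 - p2)
    return out if out.ndim else float(out)


def _design_arrays(
    data: CrosswiseCounts | pd.DataFrame,
    design: RandomizationDesign | None,
    covariates,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, RandomizationDesign, tuple[str, ...]]:
    """Normalize input to (X, y, s, weights, design, column names)."""
    if isinstance(data, CrosswiseCounts):
        design = data.design if design is None else design
        y = np.array([2, 1, 2, 1])
        s = np.array([1, 1, 2, 2])
        w = data.as_vector()
        if covariates in (None, ()):  # intercept only
            X = np.ones((4, 1))
            cols = ("intercept",)
        elif covariates == "subsample":
            X = np.column_stack([np.ones(4), (s == 2).astype(float)])
            cols = ("intercept", "subsample2")
        else:
            raise ValueError(
                "count input supports covariates=None or 'subsample'; "
                "use respondent-level data for other covariates"
            )
        return X, y, s, w, design, cols
    df = pd.DataFrame(data)
    if design is None:
        raise ValueError("a RandomizationDesign is required with respondent-level data")
    y = df["y"].to_numpy()
    s = df["s"].to_numpy()
    cov_names = list(covariates) if covariates else []
    X = np.column_stack([np.ones(len(df))] + [df[c].to_numpy(dtype=float) for c in cov_names])
    w = np.ones(len(df))
    return X, y, s, w, design, tuple(["intercept"] + cov_names)


def loglik(
    beta,
    data: CrosswiseCounts | pd.DataFrame,
    design: RandomizationDesign | None = None,
    covariates=None,
) -> float:
    """Log-likelihood of ``beta`` for ECWM data (counts or respondent-level)."""
    X, y, s, w, design, _ = _design_arrays(data, design, covariates)
    return _loglik_arrays(np.asarray(beta, dtype=float), X, y, s, w, design)


def _loglik_arrays(beta, X, y, s, w, design) -> float:
    pi_i = expit(X @ beta)
    pr = response_prob(y, s, pi_i, design)
    with np.errstate(divide="ignore"):
        lp = np.log(pr)
    return float(np.sum(np.where(w > 0, w * lp, 0.0)))


def _score_arrays(beta, X, y, s, w, design) -> np.ndarray:
    """Analytic gradient of the log-likelihood on the logit scale."""
    eta = X @ beta
    pi_i = expit(eta)
    ps = np.where(s == 1, design.p1, design.p2)
    c = 2.0 * ps - 1.0
    p2 = ps * pi_i + (1.0 - ps) * (1.0 - pi_i)
    pr = np.where(y == 2, p2, 1.0 - p2)
    sign = np.where(y == 2, 1.0, -1.0)
    r = w * sign * c * pi_i * (1.0 - pi_i) / pr
    return X.T @ r


def _numeric_hessian(grad_fn, beta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    k = beta.size
    H = np.empty((k, k))
    for j in range(k):
        step = np.zeros(k)
        step[j] = h
        H[:, j] = (grad_fn(beta + step) - grad_fn(beta - step)) / (2.0 * h)
    return (H + H.T) / 2.0


def interior_mle(counts: CrosswiseCounts) -> float:
    """Closed-form intercept-only ML estimate of pi, clipped to [0, 1].

    The intercept-only log-likelihood is concave in pi with a linear score
    equation whose root is the pooled moment estimate; the constrained
    maximizer over [0, 1] is therefore the clipped root.
    """
    d = counts.design
    if counts.n1 <= 0 or counts.n2 <= 0:
        raise EmptySubsampleError(f"{counts.label}: both sub-samples must be nonempty")
    raw = ((counts.n21 + counts.n12) / counts.n - (1.0 - d.p1)) / (2.0 * d.p1 - 1.0)
    return min(max(raw, 0.0), 1.0)


def _counts_loglik_at_pi(counts: CrosswiseCounts, pi1: float, pi2: float) -> float:
    """Multinomial log-likelihood at per-arm prevalences, 0*log(0) := 0."""
    d = counts.design
    probs = np.array(
        [
            d.p1 * pi1 + (1.0 - d.p1) * (1.0 - pi1),
            (1.0 - d.p1) * pi1 + d.p1 * (1.0 - pi1),
            d.p2 * pi2 + (1.0 - d.p2) * (1.0 - pi2),
            (1.0 - d.p2) * pi2 + d.p2 * (1.0 - pi2),
        ]
    )
    nv = counts.as_vector()
    with np.errstate(divide="ignore"):
        lp = np.log(probs)
    return float(np.sum(np.where(nv > 0, nv * lp, 0.0)))


def fit(
    data: CrosswiseCounts | pd.DataFrame,
    design: RandomizationDesign | None = None,
    covariates=None,
    gtol: float = 1e-8,
    maxiter: int = 200,
) -> EcwmFit:
    """Fit the ECWM logistic model by maximum likelihood.

    Parameters
    ----------
    data : CrosswiseCounts or DataFrame
        Aggregated counts (fitted as a weighted four-cell likelihood) or a
        respondent-level table with columns ``y``, ``s`` and covariates.
    design : RandomizationDesign, optional
        Required for respondent-level input; taken from the counts
        otherwise.
    covariates : None, "subsample", or sequence of column names
        ``None`` fits the intercept-only (prevalence) model.  With counts,
        ``"subsample"`` adds the sub-sample-membership indicator used by
        the goodness-of-fit test.

    Estimation is on the unconstrained logit scale.  The intercept-only
    score equation is linear in pi, so that model is solved exactly:
    prevalences within ``1e-6`` of 0 or 1 are flagged as boundary
    solutions with the log-likelihood evaluated at the pinned boundary.
    Regression models use BFGS from ``beta = 0`` with an analytic
    gradient (tolerance ``gtol`` on the gradient norm).  The covariance
    is the inverse of the numerically differenced observed information.
    """
    X, y, s, w, design, cols = _design_arrays(data, design, covariates)
    if np.sum(w) <= 0:
        raise EmptySubsampleError("no observations")
    k = X.shape[1]

    def ngrad(beta):
        return -_score_arrays(beta, X, y, s, w, design)

    boundary = False
    converged = True
    if k == 1:
        # The intercept-only score equation is linear in pi: solve it
        # exactly rather than iterating, and pin boundary solutions.
        n21_12 = float(np.sum(w[(y == 2) & (s == 1)]) + np.sum(w[(y == 1) & (s == 2)]))
        raw = (n21_12 / np.sum(w) - (1.0 - design.p1)) / (2.0 * design.p1 - 1.0)
        if raw <= BOUNDARY_TOL or raw >= 1.0 - BOUNDARY_TOL:
            boundary = True
            pinned = 0.0 if raw <= BOUNDARY_TOL else 1.0
            pr = response_prob(y, s, np.full(len(y), pinned), design)
            with np.errstate(divide="ignore"):
                lp = np.log(pr)
            ll = float(np.sum(np.where(w > 0, w * lp, 0.0)))
            vcov = np.full((1, 1), np.nan)
            beta = np.array([-np.inf if pinned == 0.0 else np.inf])
        else:
            beta = np.array([float(np.log(raw / (1.0 - raw)))])
    else:
        res = optimize.minimize(
            lambda b: -_loglik_arrays(b, X, y, s, w, design),
            np.zeros(k),
            jac=ngrad,
            method="BFGS",
            options={"gtol": gtol, "maxiter": maxiter},
        )
        beta = res.x
        grad_norm = float(np.max(np.abs(res.jac)))
        converged = bool(res.success or grad_norm <= 1e-4)
        if not converged:
            raise ConvergenceError(
                f"ECWM fit did not converge after {maxiter} iterations: {res.message}", res
            )

    if not boundary:
        ll = _loglik_arrays(beta, X, y, s, w, design)
        H = _numeric_hessian(ngrad, beta)
        vcov = np.linalg.inv(H)

    return EcwmFit(
        beta=beta,
        vcov=vcov,
        loglik=ll,
        converged=converged,
        boundary=boundary,
        n_obs=float(np.sum(w)),
        design=design,
        columns=cols,
    )


def prevalence_from_fit(fit_: EcwmFit, at=None) -> PrevalenceEstimate:
    """Prevalence (with delta-method Wald CI) implied by a fit at covariate
    vector ``at`` (default: intercept only, all other covariates 0).

    For boundary fits the estimate is the pinned boundary value and the
    interval is the clipped Wald interval built from the pooled moment
    variance evaluated at the boundary.
    """
    k = len(fit_.columns)
    x = np.zeros(k)
    x[0] = 1.0
    if at is not None:
        x = np.asarray(at, dtype=float)
        if x.shape != (k,):
            raise ValueError(f"covariate vector must have length {k}")

    if fit_.boundary:
        pi = 0.0 if fit_.beta[0] == -np.inf else 1.0
        var = pooled_variance(pi, fit_.n_obs, fit_.design.p1)
        half = Z95 * math.sqrt(var)
        lo = min(max(pi - half, 0.0), 1.0)
        hi = min(max(pi + half, 0.0), 1.0)
        return PrevalenceEstimate(pi, var, lo, hi, method="mle", boundary=True)

    eta = float(x @ fit_.beta)
    var_eta = float(x @ fit_.vcov @ x)
    pi = float(expit(eta))
    se = pi * (1.0 - pi) * math.sqrt(max(var_eta, 0.0))
    var = se * se
    lo = min(max(pi - Z95 * se, 0.0), 1.0)
    hi = min(max(pi + Z95 * se, 0.0), 1.0)
    return PrevalenceEstimate(pi, var, lo, hi, method="mle")


def gof_test(counts: CrosswiseCounts) -> GofResult:
    """1-df goodness-of-fit test for one ECWM question.

    Compares the intercept-only model against the sub-sample-saturated
    model (one prevalence per arm).  Both maximizers are closed-form
    (clipped linear score roots), so the test is exact and fast.  The
    p-value comes from chi-squared(1) applied to the likelihood-ratio
    statistic.
    """
    d = counts.design
    if counts.n1 <= 0 or counts.n2 <= 0:
        raise EmptySubsampleError(f"{counts.label}: both sub-samples must be nonempty")

    raw_null = ((counts.n21 + counts.n12) / counts.n - (1.0 - d.p1)) / (2.0 * d.p1 - 1.0)
    pi0 = min(max(raw_null, 0.0), 1.0)
    boundary = pi0 <= BOUNDARY_TOL or pi0 >= 1.0 - BOUNDARY_TOL

    # fitted cells under the null
    p21 = d.p1 * pi0 + (1.0 - d.p1) * (1.0 - pi0)
    p22 = d.p2 * pi0 + (1.0 - d.p2) * (1.0 - pi0)
    fitted = np.array(
        [counts.n1 * p21, counts.n1 * (1.0 - p21), counts.n2 * p22, counts.n2 * (1.0 - p22)]
    )
    obs = counts.as_vector()
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.log(obs / fitted)
    g2 = 2.0 * float(np.sum(np.where(obs > 0, obs * ratio, 0.0)))
    g2 = max(g2, 0.0)

    pi1 = min(max((counts.n21 / counts.n1 - (1.0 - d.p1)) / (2.0 * d.p1 - 1.0), 0.0), 1.0)
    pi2 = min(max((counts.n22 / counts.n2 - (1.0 - d.p2)) / (2.0 * d.p2 - 1.0), 0.0), 1.0)
    ll_full = _counts_loglik_at_pi(counts, pi1, pi2)
    ll_null = _counts_loglik_at_pi(counts, pi0, pi0)
    lr = max(2.0 * (ll_full - ll_null), 0.0)

    return GofResult(
        lr_stat=lr,
        g2_stat=g2,
        df=1,
        p_value=float(chi2.sf(lr, 1)),
        boundary=boundary,
    )
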