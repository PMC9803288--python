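"""Respondent-level simulation, estimator validation, and power analysis.

The generator draws each respondent's carrier status, unrelated-question
outcome, and reported crosswise response under three behavioral regimes:

* truthful responding (the clean ECWM model),
* informed self-protection: with probability ``theta_c`` (carriers) or
  ``theta_nc`` (non-carriers) the respondent emits the safe response for
  their arm — the response less indicative of carrying the attribute,
* random responding: with some probability the respondent picks a
  response uniformly, independent of everything, which pulls prevalence
  estimates toward 50%.

On top of the generator sit a parameter-recovery harness (bias, RMSE, CI
coverage over replications), a Monte-Carlo calibration check of the 1-df
goodness-of-fit statistic against chi-squared(1), and analytic +
Monte-Carlo power for the Wald test of zero prevalence.  Because informed
self-protection only reweights the four cell probabilities while
preserving the model's row symmetries, the goodness-of-fit test has no
power against it; :func:`expected_counts` makes that non-identifiability
exact and checkable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .dq_compare import DirectCounts
from .mle import gof_test
from .model_core import (
    CrosswiseCounts,
    InvalidDesignError,
    RandomizationDesign,
    SelfProtectionParams,
    moment_pooled,
    pooled_variance,
    sp_transition_matrix,
    transition_matrix,
)

__all__ = [
    "SimulationConfig",
    "RecoverySummary",
    "GofCalibration",
    "PowerResult",
    "simulate_ecwm",
    "simulate_dq",
    "expected_counts",
    "recover",
    "gof_calibration",
    "analytic_power",
    "power",
]

#: chi-squared(1) upper 5% critical value used in calibration summaries.
CHI2_1_CRIT = 3.841


@dataclass(frozen=True)
class SimulationConfig:
    """Scenario description for one simulated ECWM question.

    ``n1``/``n2`` are fixed sub-sample sizes (allocation is deterministic,
    mirroring designed alternation of arms rather than a random split).
    ``dq_report_prob`` is the chance that a carrier admits the attribute
    under direct questioning; non-carriers never false-confess.
    """

    pi: float
    design: RandomizationDesign = field(default_factory=lambda: RandomizationDesign(0.8))
    n1: int = 367
    n2: int = 367
    theta: SelfProtectionParams = field(default_factory=SelfProtectionParams)
    random_responder_frac: float = 0.0
    dq_report_prob: float = 1.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("pi", "random_responder_frac", "dq_report_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability, got {v}")
        if self.n1 < 0 or self.n2 < 0:
            raise ValueError("sub-sample sizes must be nonnegative")


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of estimator performance against the truth."""

    mean_estimate: float
    bias: float
    rmse: float
    ci_coverage: float
    reps: int


@dataclass(frozen=True)
class GofCalibration:
    """Rejection rate of the goodness-of-fit test plus the raw statistics."""

    rejection_rate: float
    stats: np.ndarray
    critical_value: float
    reps: int


@dataclass(frozen=True)
class PowerResult:
    """Analytic (and optionally Monte-Carlo) power over a grid of total n."""

    n_grid: np.ndarray
    power: np.ndarray
    min_n: int | None
    target: float
    mc_power: np.ndarray | None = None


def _cell_probs(config: SimulationConfig) -> np.ndarray:
    """Exact cell probabilities (2|1, 1|1, 2|2, 1|2) under the configured
    behavior mixture.  Self-protection uses the Q transition matrix;
    random responders contribute a flat 1/2 to both responses."""
    d, th = config.design, config.theta
    if th.theta_c > 0 or th.theta_nc > 0:
        M = sp_transition_matrix(d, th)
    else:
        M = transition_matrix(d)
    base = M @ np.array([config.pi, 1.0 - config.pi])
    f = config.random_responder_frac
    return (1.0 - f) * base + f * 0.5


def simulate_ecwm(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, CrosswiseCounts]:
    """Simulate one ECWM question at the respondent level.

    Returns the respondent table (with the latent truth columns retained
    for validation) and the aggregated 2x2 count table.  Identical config
    and seed give identical output.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = config.design
    n1, n2 = config.n1, config.n2
    n = n1 + n2
    s = np.concatenate([np.ones(n1, dtype=int), np.full(n2, 2, dtype=int)])
    ps = np.where(s == 1, d.p1, d.p2)

    carrier = rng.random(n) < config.pi
    unrelated_yes = rng.random(n) < ps
    y = np.where(carrier == unrelated_yes, 2, 1)

    theta_i = np.where(carrier, config.theta.theta_c, config.theta.theta_nc)
    self_protective = rng.random(n) < theta_i
    safe = np.where(ps > 0.5, 1, 2)  # the response less indicative of a carrier
    y = np.where(self_protective, safe, y)

    random_responder = rng.random(n) < config.random_responder_frac
    y = np.where(random_responder, rng.integers(1, 3, size=n), y)

    df = pd.DataFrame(
        {
            "y": y,
            "s": s,
            "carrier": carrier,
            "unrelated_yes": unrelated_yes,
            "self_protective": self_protective & ~random_responder,
            "random_responder": random_responder,
        }
    )
    counts = CrosswiseCounts(
        label="simulated",
        n21=int(np.sum((y == 2) & (s == 1))),
        n11=int(np.sum((y == 1) & (s == 1))),
        n22=int(np.sum((y == 2) & (s == 2))),
        n12=int(np.sum((y == 1) & (s == 2))),
        design=d,
    )
    return df, counts


def simulate_dq(
    pi: float,
    dq_report_prob: float,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> DirectCounts:
    """Simulate a direct-question condition with carrier underreporting:
    yes-count ~ Binomial(n, pi * dq_report_prob)."""
    if not (0.0 <= pi <= 1.0 and 0.0 <= dq_report_prob <= 1.0):
        raise ValueError("pi and dq_report_prob must be probabilities")
    if rng is None:
        rng = np.random.default_rng(seed)
    n_yes = int(rng.binomial(n, pi * dq_report_prob))
    return DirectCounts(n_yes=n_yes, n_no=n - n_yes)


def expected_counts(config: SimulationConfig, label: str = "expected") -> CrosswiseCounts:
    """Noise-free expected count table: sub-sample sizes times the exact
    cell probabilities of the configured behavior mixture.  Feeding these
    to the estimators reveals probability limits (e.g. the exact
    self-protection bias) without Monte-Carlo error."""
    probs = _cell_probs(config)
    return CrosswiseCounts(
        label=label,
        n21=config.n1 * probs[0],
        n11=config.n1 * probs[1],
        n22=config.n2 * probs[2],
        n12=config.n2 * probs[3],
        design=config.design,
    )


def _simulate_count_vectors(
    config: SimulationConfig, reps: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized draw of (n21, n22) across replications.

    Within each arm the individual behaviors are independent, so the cell
    counts are binomial in the exact mixture cell probabilities; this is
    distributionally identical to aggregating respondent-level draws."""
    probs = _cell_probs(config)
    n21 = rng.binomial(config.n1, probs[0] / (probs[0] + probs[1]), size=reps)
    n22 = rng.binomial(config.n2, probs[2] / (probs[2] + probs[3]), size=reps)
    return n21, n22


def recover(
    config: SimulationConfig, reps: int, rng: np.random.Generator | None = None
) -> RecoverySummary:
    """Repeatedly simulate and re-estimate to measure bias, RMSE, and the
    coverage of the 95% Wald interval against the true prevalence.

    The point estimate assessed is the pooled moment estimator, which is
    also the interior maximum-likelihood estimate."""
    if reps < 1:
        raise ValueError("reps must be at least 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    estimates = np.empty(reps)
    covered = np.empty(reps, dtype=bool)
    for r in range(reps):
        try:
            _, counts = simulate_ecwm(config, rng=rng)
            est = moment_pooled(counts)
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"estimation failed in replication {r}") from exc
        estimates[r] = est.pi_hat
        covered[r] = est.ci_low <= config.pi <= est.ci_high
    mean_est = float(np.mean(estimates))
    bias = mean_est - config.pi
    rmse = float(np.sqrt(np.mean((estimates - config.pi) ** 2)))
    return RecoverySummary(
        mean_estimate=mean_est,
        bias=bias,
        rmse=rmse,
        ci_coverage=float(np.mean(covered)),
        reps=reps,
    )


def gof_calibration(
    config: SimulationConfig,
    reps: int,
    rng: np.random.Generator | None = None,
    flip_arm: int | None = None,
) -> GofCalibration:
    """Monte-Carlo distribution of the goodness-of-fit LR statistic.

    Under the clean model the rejection rate at the chi-squared(1) 5%
    critical value should be near 0.05.  Data contaminated by informed
    self-protection stay calibrated too (the bias cancels across arms);
    ``flip_arm`` flips the responses of one sub-sample after generation,
    a detectable distortion, to exercise the test's power."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n21, n22 = _simulate_count_vectors(config, reps, rng)
    stats = np.empty(reps)
    for r in range(reps):
        c21, c22 = int(n21[r]), int(n22[r])
        c11, c12 = config.n1 - c21, config.n2 - c22
        if flip_arm == 1:
            c21, c11 = c11, c21
        elif flip_arm == 2:
            c22, c12 = c12, c22
        counts = CrosswiseCounts("calib", c21, c11, c22, c12, config.design)
        stats[r] = gof_test(counts).lr_stat
    return GofCalibration(
        rejection_rate=float(np.mean(stats > CHI2_1_CRIT)),
        stats=stats,
        critical_value=CHI2_1_CRIT,
        reps=reps,
    )


def analytic_power(
    pi_alt: float,
    design: RandomizationDesign,
    n: int,
    alpha: float = 0.05,
    allocation: float = 0.5,
) -> float:
    """Analytic power of the two-sided Wald test of H0: pi = 0 against
    pi = pi_alt at total sample size ``n``.

    The test statistic is ``pi_hat / sqrt(V0)`` with the null variance
    (the unrelated-question noise term only); power is evaluated with the
    alternative variance.  ``allocation`` is the fraction of n in
    sub-sample 1 and only enters through the total (the pooled variance
    depends on n alone)."""
    if not 0.0 < pi_alt < 1.0:
        raise ValueError("pi_alt must lie strictly between 0 and 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if not 0.0 < allocation < 1.0:
        raise ValueError("allocation must lie strictly between 0 and 1")
    if design.p1 == 0.5:
        raise InvalidDesignError("p1 = 0.5 has infinite estimator variance")
    v0 = pooled_variance(0.0, n, design.p1)
    v1 = pooled_variance(pi_alt, n, design.p1)
    crit = norm.ppf(1.0 - alpha / 2.0) * np.sqrt(v0)
    sd1 = np.sqrt(v1)
    return float(
        norm.sf((crit - pi_alt) / sd1) + norm.cdf((-crit - pi_alt) / sd1)
    )


def power(
    pi_alt: float,
    design: RandomizationDesign,
    n_grid,
    alpha: float = 0.05,
    allocation: float = 0.5,
    target: float = 0.8,
    mc_reps: int | None = None,
    seed: int | None = None,
) -> PowerResult:
    """Power curve over a grid of total sample sizes, with the smallest n
    reaching ``target`` power, and an optional Monte-Carlo verification.

    The Monte-Carlo mode simulates clean-model data at ``pi_alt`` and
    applies the same null-variance Wald test as the analytic formula."""
    n_grid = np.asarray(sorted(int(n) for n in np.atleast_1d(n_grid)))
    pw = np.array([analytic_power(pi_alt, design, n, alpha, allocation) for n in n_grid])
    reaching = n_grid[pw >= target]
    min_n = int(reaching[0]) if reaching.size else None

    mc = None
    if mc_reps:
        rng = np.random.default_rng(seed)
        zcrit = norm.ppf(1.0 - alpha / 2.0)
        mc = np.empty(len(n_grid))
        for i, n in enumerate(n_grid):
            n1 = int(round(allocation * n))
            n2 = int(n) - n1
            cfg = SimulationConfig(pi=pi_alt, design=design, n1=n1, n2=n2)
            n21, n22 = _simulate_count_vectors(cfg, mc_reps, rng)
            pi1 = (n21 / n1 - (1.0 - design.p1)) / (2.0 * design.p1 - 1.0)
            pi2 = (n22 / n2 - (1.0 - design.p2)) / (2.0 * design.p2 - 1.0)
            pi_hat = (n1 * pi1 + n2 * pi2) / n
            v0 = pooled_variance(0.0, n, design.p1)
            mc[i] = float(np.mean(np.abs(pi_hat) / np.sqrt(v0) > zcrit))
    return PowerResult(n_grid=n_grid, power=pw, min_n=min_n, target=target, mc_power=mc)
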