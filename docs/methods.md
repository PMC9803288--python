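# Methods

## Observation model

A crosswise item records, for respondent *i* in sub-sample *s* ∈ {1, 2},
the match indicator between a sensitive answer and an unrelated answer:

    P(y = 2 | s) = p_s π + (1 − p_s)(1 − π),      p_2 = 1 − p_1,

where `y = 2` means "TWO 'Yes' or TWO 'No'" and π is the prevalence of
the sensitive attribute. `p1 = 0.5` is excluded by construction (the
inverse mapping divides by `2p1 − 1`); `p1 ∈ {0, 1}` is admitted only for
control items with known prevalence. Assumptions: respondents in both
arms share the same π (randomized allocation), the unrelated-question
probability is exactly the designed value (this is what the
number-sequence randomizer buys over birthday-based randomizers), and
responses are independent across respondents.

## Estimators

**Moment.** Per arm, `π̂_s = (n_{2s}/n_s − 1 + p_s)/(2p_s − 1)`; pooled as
the sub-sample-size weighted average. Variance
`V(π̂) = [π(1−π) + p1(1−p1)/(2p1−1)²]/n`, evaluated at the pooled estimate
with the binomial term clipped to [0, 1] so that out-of-range moment
estimates (which are deliberately *not* clipped, being a useful
diagnostic) cannot yield a negative variance. Confidence intervals are
Wald at z = 1.959964, truncated to [0, 1].

**Matrix moment.** `π̂ = 2·P⁻·f` with P the 4×2 transition matrix,
P⁻ its Moore–Penrose inverse (numpy.linalg.pinv), and f the unconditional
cell proportions; variance from the sandwich
`4/n · P⁻ (diag f − f f′) P⁻′`. Equal to the pooled moment estimator
when the arms are balanced (tested to machine precision).

**Maximum likelihood.** `π_i = expit(x_i′β)` maximized over β. The
intercept-only score equation is *linear* in π, with root equal to the
pooled moment estimate; the package therefore solves that model exactly
(clipping the root into [0, 1]) rather than iterating, which makes
boundary detection exact: a root within 1e-6 of 0 or 1 is flagged, the
prevalence pinned, and the log-likelihood evaluated at the boundary.
Regression models are fit by BFGS on the unconstrained logit scale from
β = 0 with the analytic gradient
`Σ w_i ±(2p_s−1) π_i(1−π_i)/π*_yi x_i` (gradient tolerance 1e-8, max 200
iterations; non-convergence raises with the optimizer trace attached).
The coefficient covariance is the inverse of the observed information,
obtained by central-differencing the analytic gradient (step 1e-5).
Prevalences and their standard errors are mapped back with the delta
method, `SE(π̂) = π̂(1−π̂)·SE(x′β̂)`.

Two variances are thus available for an intercept-only prevalence: the
closed-form pooled (moment) variance and the observed-information delta
variance. They agree to within ~2% on balanced interior data; the pooled
form is the reporting default (it reproduces the published intervals) and
the delta form is what `prevalence_from_fit` returns for regression fits.

## Goodness of fit

Null: intercept-only; alternative: one prevalence per arm (saturated in
the sub-sample dimension, 1 df). Both maximizers are clipped linear score
roots, so `gof_test` is closed-form. It reports the likelihood-ratio
statistic, the discrepancy `G² = 2Σ n_ys ln(n_ys/n̂_ys)` against the
observed table (0·ln 0 := 0), and a χ²(1) p-value of the LR statistic.
The two statistics are equal (tested to 1e-6) unless the null solution is
on the boundary, where LR = 0 while G² > 0 — the boundary flag marks this.
A test cross-checks the closed-form LR against the optimization route
(twice the log-likelihood gap between fits with and without the
sub-sample covariate).

## Informed self-protection

With carriers (non-carriers) diverting from their arm's incriminating
response at rate θ_c (θ_nc), the transition matrix becomes

    rows 1, 4: ( p1(1−θ_c),      (1−θ_nc)(1−p1) )
    rows 2, 3: ( 1 − p1(1−θ_c),  p1 + θ_nc(1−p1) ),

for the convention p1 > p2. The second row is fixed by column-
stochasticity (each column of a sub-sample block must sum to 1) and by
the preserved equality of rows 1/4 and 2/3. That preserved symmetry is
the whole point: contaminated expected counts fit the clean model with
G² exactly 0, so θ_c, θ_nc are unidentified and undetectable, while the
naive estimator converges to a biased limit
(`π(1 − p1θ_c/(2p1−1))` when θ_nc = 0, negative for large θ_c). The
simulator reproduces this exactly via `expected_counts` and
stochastically via Monte Carlo.

## Simulator

`simulate_ecwm` draws, per respondent: carrier status Bernoulli(π),
fixed arm membership (deterministic n1/n2 split, mirroring designed
alternation rather than random splitting), unrelated answer
Bernoulli(p_s), the truthful match response, then the two contamination
layers — informed self-protection at the per-status θ rate (emitting the
safe response for the arm, i.e. the one less indicative of carrying when
p_s > 0.5) and uniform random responding, which overrides everything and
pulls both response fractions toward 1/2. Latent truth columns are kept
for validation. One `numpy` Generator per run; the same config and seed
reproduce identical output.

Because behaviors are iid within an arm, the aggregated cell counts are
exactly binomial in the mixture cell probabilities; `gof_calibration` and
the Monte-Carlo power mode use that equivalent vectorized form to keep
2000-replication runs near-instant, while `recover` exercises the full
respondent-level path.

What the generator does *not* emulate: survey fatigue/recall errors on
the randomizer (empirically these scale with sequence length; they enter
the toolkit only through the control-question error-rate comparison),
non-uniform randomizer selection, covariate-dependent prevalence in the
scenario defaults, and panel effects. Passing recovery/calibration tests
therefore validates the estimators under the stated behavioral model,
not the field behavior of any particular survey.

**Default scenario sizes.** Calibration runs use 367 respondents per arm
(the scale of one study question's arms, e.g. 361/373) with π = 0.3 and
p1 = 0.8, 2000 replications; recovery uses 5000 per arm and 500
replications; Monte-Carlo power verification 2000 replications at
n = 734. Under these conditions the GOF rejection rate at the 3.84
cutoff is 0.05 ± 0.01, |bias| < 0.01 with CI coverage in [0.93, 0.97],
and analytic power matches Monte-Carlo power within 0.02 (all asserted
by the test suite).

## Power

Defined as the two-sided Wald test of H0: π = 0 against π = π_alt using
the *null* variance (only the randomizer noise term, since π(1−π) = 0 at
the null) to form the critical value and the alternative variance for the
power integral; the Monte-Carlo mode applies the identical decision rule
to simulated data, so the two modes estimate the same quantity by
construction. Defaults: α = 0.05, equal allocation, target power 0.8.
The test specification (null, sidedness, α) is an explicit argument
rather than a hard-coded choice.

## Number-sequence randomizer

First sequences are drawn without replacement from the 72 admissible
two-digit numbers (10–99 minus the nine repdigits and nine multiples of
ten, excluded as too memorable or preferentially chosen). Exactly
`L·p` of them are planted into the second sequence (supported designs:
L ∈ {5, 10, 15}, p ∈ {0, 1/5, 4/5, 1}); filler slots draw from 1–99
excluding all first-sequence members, with no memorability exclusions —
the exclusions exist to control which number the respondent memorizes,
not what appears in the lookup sequence. Both sequences are kept
duplicate-free (a duplicate would corrupt the overlap probability).
For p = 1 (control items) the second sequence is the first reshuffled,
re-drawn until visibly reordered. Probabilities are exact rationals
(`fractions.Fraction`), never floats. Survey sheets alternate the
1/5–4/5 assignment between consecutive questions with complementary arms
per question; filler draws are independent across questions.

## Numerical conventions and edge cases

- Canonical cell order everywhere: (2|1, 1|1, 2|2, 1|2).
- Sub-sample 1 is the p = 1/5 arm in the bundled data; all estimators are
  invariant to relabeling arms with the complementary p (property-tested).
- Count containers accept non-integer values so expected-count tables flow
  through the estimation code unchanged.
- Empty sub-samples and p1 = 0.5 raise typed errors
  (`EmptySubsampleError`, `InvalidDesignError`) at the earliest point.
- Reports print percentages to 1 decimal, statistics to 2, p-values to 3;
  CSV/JSON outputs keep full precision.

## Known limitations

- The self-protection bias algebra assumes p1 > 0.5 (the convention that
  makes "the safe response" well defined); the simulator generalizes by
  choosing the safe response per arm from p_s.
- Boundary fits report the pooled variance evaluated at the boundary as a
  pragmatic interval; a profile-likelihood interval would be preferable
  for small boundary samples.
- Published confidence-interval digits can differ from the exact Wald
  computation by one unit in the last printed decimal; point estimates,
  G² and z statistics reproduce exactly.
- No multiplicity adjustment across questions is applied (questions are
  processed independently).
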