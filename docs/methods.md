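# Methods

This note records the statistical model, the numerical choices, and the
limits of what the package's tests demonstrate.

## Data model

A cohort is a set of N subjects, each contributing a follow-up time
T̃ᵢ > 0 (years from a common origin), an event indicator dᵢ ∈ {0, 1}, and
a case weight wᵢ > 0. Censoring is assumed independent of the event
process. The event is a single composite endpoint; competing risks,
left truncation, interval censoring and covariates are out of scope.
Zero follow-up times are rejected rather than jittered: a subject with no
time at risk has no defined contribution to the estimators, and silently
perturbing data is worse than refusing it.

Weights are real-valued frequency weights throughout: they scale event
and at-risk counts in the nonparametric estimator and the log-likelihood
terms in the parametric fits. This is what makes the ghost construction
coherent on both sides of the comparison.

## Nonparametric estimator

The weighted Nelson–Aalen cumulative hazard is H(t) = Σ d_i/Y_i over
distinct event times, with the Poisson-type variance V(t) = Σ d_i/Y_i².
The Greenwood-style alternative Σ d_i(Y_i−d_i)/Y_i³ would differ only in
the third decimal at the sample sizes of interest, and both scale
identically under uniform weighting, so ghost counts are insensitive to
the choice; the estimator used is recorded in the curve metadata. Risk is
F̂ = 1 − e^(−H) with delta-method SE(F̂) = e^(−H)√V.

Confidence limits are identity-scale Wald, F̂ ± z₀.₉₇₅ SE, with
z₀.₉₇₅ = 1.959963985… (the exact quantile; pass `z=1.96` for
rounded-quantile mimicry). Limits are deliberately not transformed
(log(−log)) and not clipped to [0, 1]: the CL *width* is the efficiency
currency here, and the identity scale makes the width exactly 2z·SE,
symmetric about the estimate. Ties between events and censorings at the
same time follow the universal convention: events occur first, censored
subjects then leave the risk set.

The load-bearing property is the **weight-scaling law**: replacing every
wᵢ by c·wᵢ leaves H and F̂ unchanged (d/Y is scale-free) and divides every
SE by √c. It holds to floating-point rounding (~1e-15 relative) and is
tested at 1e-12.

## Parametric families

All three families are accelerated-failure-time models on the log-time
axis, log T = μ + σW. With z = (log t − μ)/σ and a = κ⁻²:

- generalized gamma (free μ, σ > 0, κ): S(t) = 1 − G(a·e^(κz); a) for
  κ > 0, S(t) = G(a·e^(κz); a) for κ < 0, where G(·; a) is the
  regularized lower incomplete gamma function; κ → 0 is the lognormal
  limit 1 − Φ(z).
- Weibull: the κ = 1 sub-family, S(t) = exp(−(t·e^(−μ))^(1/σ)).
- exponential: additionally σ = 1; constant hazard λ = e^(−μ).

Below |κ| < 1e-4 the code switches to the lognormal limit for survival,
density and likelihood. The switch keeps every quantity continuous to
O(1e-4) — far below the statistical noise at any realistic sample size —
and avoids evaluating incomplete gamma functions at shapes beyond 1e8,
where their accuracy degrades.

### Fitting

The weighted censored log-likelihood Σ wᵢ[dᵢ log f(tᵢ) + (1−dᵢ) log S(tᵢ)]
is maximized on the unconstrained scale (μ, log σ, κ) with L-BFGS-B,
multi-started from (i) the nested simpler fit (exponential → Weibull →
generalized gamma, which also guarantees the nested log-likelihood
ordering up to optimizer tolerance) and (ii) method-of-moments values on
the log event times. The generalized-gamma likelihood is notoriously
ridged in κ, so its L-BFGS-B solution is additionally polished with a
Nelder–Mead pass. Box bounds (|μ| ≤ 30, log σ ∈ [−6, 4], |κ| ≤ 6) only
exclude regions where the likelihood under/overflows. Convergence is
reported honestly: a failed fit carries `converged=False` and a warning,
and `parametric_risk_curve` refuses it unless forced.

The covariance of the estimates is the inverse of the observed
information, computed by central finite differences at the optimum and
mapped to the natural (μ, σ, κ) scale by the delta method. The Hessian
step is 1.2e-4 relative (≈ eps^¼): second differences at a 1e-5 step lose
~3 significant digits to round-off, which would be visible against the
1e-6 agreement the exponential closed form provides; at eps^¼ both
truncation and round-off sit near 1e-8. First-derivative (risk gradient)
steps are 1e-5 relative; both steps are recorded in the fit metadata.

Risk limits are again identity-scale Wald with SE(F̂(t)) = √(gᵀ Σ̂ g),
g the central-difference gradient of F(t) in the free parameters. For
the exponential family this reproduces the analytic delta method
SE = t·e^(−λt)·λ/√D to better than 1e-6 relative, which is the accuracy
anchor for the numeric path.

## Ghost augmentation

Adding M ghosts multiplies every weight by (N+M)/N. The search for the
smallest M whose weighted nonparametric CL width at the evaluation time
falls **strictly below** the parametric target width iterates M one by
one, evaluating each step through the exact scaling law
width(M) = width₀/√(1 + M/N); a `refit=True` mode literally re-runs the
Nelson–Aalen estimator per step as a validation path and gives identical
counts. The strict inequality is the stopping rule, so a width exactly
equal to the target does not stop the search — the equality boundary is
exercised by a dedicated test. `closed_form_ghosts` solves the same
problem analytically, refining the candidate ⌊N((width₀/target)² − 1)⌋ + 1
by evaluating the stopping predicate itself at the neighbouring integers;
agreement between the two routes on random inputs (including constructed
exact-equality boundaries) is the module's defining correctness property.

Because the risk estimate is weight-invariant, the achieved width times
√(1 + M/N) recovers the unweighted width to machine precision, and
(N+M)/N can be read directly as an effective-sample-size ratio.

Comparison at a single evaluation time (default 2 years) is the primary
mode; `average_cl_width` additionally supports matching the mean width
over the event-time grid as a curve-wide extension.

## Synthetic cohorts

`generate_cohort` emulates a single-arm observational cohort: event times
from one of the three AFT families (generalized-gamma sampling is exact,
via a Gamma(κ⁻²) deviate pushed through the AFT transform, not
accept–reject), independent exponential loss to follow-up, and a fixed
administrative horizon. Recorded time is the minimum of the three; one
integer seed determines everything and no global RNG state is touched.
The LTFU mechanism draws from an inverse-CDF uniform stream, so cohorts
generated from the same seed at different LTFU rates are coupled
subject-by-subject (common random numbers), which makes the event
fraction exactly monotone in the LTFU rate.

The default scenario models a cohort of 1164 subjects followed for up to
10.83 years. Its event-time distribution was calibrated once
(`scripts/calibrate_default_scenario.py`) to a generalized gamma with
κ = 0.75 and (μ, σ) solved so the true two-year risk is 0.218 and the
ten-year risk 0.45, with a 5%/year LTFU hazard — values chosen to be
realistic for a late-1990s HIV cohort with roughly 40% cumulative
incidence over a decade and moderate attrition. The calibrated constants
are hard-coded so the scenario is a stable fixture, not a moving target.
Simulated cohorts reproduce the intended observables (median two-year
nonparametric risk ≈ 0.217, two-year CL width ≈ 0.049).

What the generator does **not** emulate: covariates and their
confounding structure, visit-schedule-driven interval censoring,
non-exponential or informative dropout, and calendar-time trends.
Passing tests therefore demonstrate the estimators' internal correctness
and calibration under independent censoring — not robustness to the
messier features of real cohort data.

## Efficiency metrics

CL width at t, its unweighted mean over the distinct event times of the
reference cohort (parametric curves are evaluated on that same grid, not
a uniform one), and RMSE = √(bias² + SE²) with bias measured against the
nonparametric estimate treated as unbiased. RMSE is offered in a
pointwise mode (at the evaluation time) and a curve-mean mode (averaged
over the event-time grid) because the aggregation window behind a single
published RMSE number is generally ambiguous; the mode is always recorded
and neither is treated as more canonical.

`build_comparison_table` assembles the seven-row comparison (1
nonparametric + 3 parametric + 3 matched weighted-nonparametric rows),
ordered by descending CL width within blocks; display output rounds
half-even to 3 decimals, machine output keeps full precision.

## Problem sizes in the test suite

Property tests run on cohorts of up to a few hundred subjects; the
frequentist coverage check uses 500 replicates of n = 1000 Weibull
cohorts; parameter recovery uses n = 5000; distributional fidelity (KS)
uses n = 1e5 draws; the efficiency-ordering check uses 10 default-scenario
cohorts at n = 1164. These sizes give comfortable statistical resolution
for each claim (e.g. binomial SE ≈ 1% on the coverage proportion) while
keeping the full suite under a minute on a laptop-class machine.

## Known limitations

- Identity-scale Wald limits can cross 0 or 1 near the extremes of the
  risk scale; they are left unclipped because the width, not the
  location, is the quantity of interest.
- The observed-information covariance assumes an interior optimum;
  gengamma fits whose κ̂ lands on the box bound are flagged as
  non-converged rather than repaired.
- The ghost count is specific to the evaluation time and to the CL-width
  efficiency metric; it is not a general-purpose effective sample size.
- Weighted fits treat weights as frequencies. Survey-style
  (design-weight) variance estimation is a different construction and is
  not provided.
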