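# ghostrisk

**Parametric efficiency gains in survival analysis, counted as hidden
observations.**

When estimating a cumulative risk curve from right-censored time-to-event
data, an analyst can choose a nonparametric estimator (flexible, but with
wide confidence limits) or a parametric model (narrow limits, but biased if
the assumed form is wrong). `ghostrisk` makes the price of that choice
concrete: it measures *how many extra subjects the nonparametric analysis
would need* before its confidence limits become as tight as a parametric
model's. Those extra subjects are the "ghosts" — the hidden observations
implicitly contributed by the parametric form assumption.

The package is aimed at epidemiologists and biostatisticians teaching or
exploring the bias–variance trade-off in survival modelling, and ships a
synthetic-cohort generator modelled on an HIV cohort study design
(N = 1164, ~10.8 years of follow-up) so everything runs without access to
confidential data.

## The method

For a cohort of nominal size N with distinct event times t_i, weighted
event counts d_i and weighted at-risk counts Y_i:

- **Nonparametric risk** (Nelson–Aalen): H(t) = Σ_{t_i ≤ t} d_i/Y_i,
  F̂(t) = 1 − e^(−H(t)), with hazard variance V(t) = Σ d_i/Y_i² and
  delta-method SE(F̂) = e^(−H)·√V. 95% limits are identity-scale Wald,
  F̂ ± z₀.₉₇₅·SE.
- **Parametric risk**: censored maximum likelihood for the accelerated
  failure time families log T = μ + σW — 1-parameter exponential,
  2-parameter Weibull, and the 3-parameter generalized gamma
  (shape κ; κ = 1 gives Weibull, κ → 0 lognormal). Pointwise limits again
  by the delta method, SE(F̂(t)) = √(gᵀ Σ̂ g).
- **Ghosts**: add pseudo-observations one at a time, each realized as a
  uniform weight increment of 1/N on every real subject, so the estimated
  curve never moves while every SE shrinks by the exact factor
  √(1 + M/N). The ghost count for a parametric model is the smallest M at
  which the weighted nonparametric CL width at the evaluation time (2
  years by default) drops strictly below the parametric width. (N + M)/N
  is then the effective-sample-size ratio bought by the model-form
  assumption.

The comparison metrics are the CL width ("CL difference") at the
evaluation time, its average over all distinct event times, and the RMSE
√(bias² + SE²) against the nonparametric estimate treated as unbiased.

## Worked example

Simulate a cohort from the default scenario (N = 1164, generalized-gamma
event times, 5%/year loss to follow-up, administrative censoring at 10.83
years) and compare all four models at two years:

```bash
ghostrisk simulate --seed 1 --out wihs_like.csv
ghostrisk compare --in wihs_like.csv --at 2.0
```

```
     approach    n    m  risk cl_lower cl_upper cl_difference avg_cl_difference  rmse
nonparametric 1164    0 0.211    0.187    0.235         0.048             0.044 0.012
     gengamma 1164    0 0.211    0.190    0.232         0.042             0.039 0.011
nonparametric 1164  331 0.211    0.190    0.232         0.042             0.039 0.011
      weibull 1164    0 0.212    0.192    0.232         0.040             0.038 0.010
nonparametric 1164  479 0.211    0.191    0.231         0.040             0.037 0.010
  exponential 1164    0 0.129    0.118    0.140         0.022             0.025 0.082
nonparametric 1164 4317 0.211    0.200    0.222         0.022             0.020 0.006
```

Read the table in pairs. The generalized gamma fits the nonparametric
curve closely (risk 0.211 vs 0.211) and its tighter limits (0.042 vs
0.048) are worth M = 331 hidden observations — the nonparametric analysis
would need 1164 + 331 subjects to match it. The exponential model is far
more precise (width 0.022) but badly biased (risk 0.129 vs 0.211, RMSE
0.082): its strict one-parameter form is worth 4317 ghosts, precision
bought at the cost of specification bias. The same comparison for a
single model, with the search trajectory:

```bash
ghostrisk ghosts --in wihs_like.csv --model gengamma --at 2.0
# N = 1164, target (gengamma) width = 0.042
# unweighted nonparametric width = 0.048
# M = 331 pseudo-observations (weight 1.284364) -> width 0.042
```

The same workflow is available as a library: `generate_cohort`,
`nelson_aalen_curve`, `fit_parametric`, `parametric_risk_curve`,
`find_ghosts`, `build_comparison_table` (see the module docstrings).

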