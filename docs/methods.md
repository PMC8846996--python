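# Methods

## Model and likelihood

The joint model couples a linear mixed model for a Gaussian longitudinal
outcome with proportional cause-specific hazards for a competing-risks
event time through shared random effects bᵢ ~ N_q(0, Σ):

- Yᵢⱼ = xᵢⱼᵀβ + zᵢⱼᵀbᵢ + εᵢⱼ, εᵢⱼ ~ N(0, σ²) independent across visits;
- λₖ(t | Xᵢ⁽²⁾, bᵢ) = λ₀ₖ(t)·exp(γₖᵀXᵢ⁽²⁾ + νₖᵀbᵢ), k = 1..K, with
  unspecified baselines; censoring (cause 0) independent of the event
  mechanism given covariates.

The observed-data likelihood integrates the product of the two conditional
densities and the random-effects prior over bᵢ. The nonparametric
baselines are estimated as step functions with jumps only at the distinct
observed event times of each cause; ties are collapsed Breslow-style into
one jump with multiplicity dₖⱼ. Risk sets are closed: R(t) = {r : T_r ≥ t},
so a subject censored exactly at an event time is still at risk there.

## EM algorithm

Treating bᵢ as missing data, each iteration is a generalised EM:

1. **E-step.** Per-subject posterior moments of bᵢ by Gauss–Hermite
   quadrature (below), requiring Λ₀ₖ(Tᵢ) for every subject — produced by
   the linear step-function lookup, never by per-subject search.
2. **M-step, Gaussian block (closed form).**
   β = (Σxxᵀ)⁻¹Σx(Y − zᵀE[b]); σ² = N⁻¹Σ{(Y−xᵀβ)² − 2(Y−xᵀβ)zᵀE[b] +
   zᵀE[bbᵀ]z}; Σ = n⁻¹ΣE[bᵢbᵢᵀ]. These maximise the expected
   complete-data log-likelihood; the test suite certifies a vanishing
   finite-difference gradient at the update.
3. **M-step, baselines (closed form).** Breslow jumps
   ΔΛ₀ₖ(tₖⱼ) = dₖⱼ / Σ_{r∈R(tₖⱼ)} e^{γₖᵀX_r}E[e^{νₖᵀb_r}], all
   denominators from one suffix-sum scan per risk.
4. **M-step, survival coefficients.** One Newton–Raphson step on the
   stacked (γₖ, νₖ) with the fresh baseline held fixed. The score stacks
   the event-time sums dₖⱼS¹ₖⱼ/S⁰ₖⱼ; the expected information is
   Σⱼ ΔΛₖⱼ Σ_{r∈R} e^{γᵀX}·{E[e^{νᵀb}]XXᵀ, E[be^{νᵀb}]Xᵀ, E[bbᵀe^{νᵀb}]},
   every aggregate again one linear scan. The step is halved (≤10 times)
   if the expected complete-data objective would decrease; the objective
   at a trial ν is evaluated exactly from the stored posterior grid
   weights, so halving needs no new density evaluations.

Because the baseline update maximises Q over the baselines at the current
(γ, ν) and the Newton step then cannot decrease Q at the fixed baseline,
the observed log-likelihood ascends monotonically whenever the quadrature
measure is fixed — which it is for the pseudo-adaptive rule. Convergence:
max relative parameter change < 1e-4 or relative log-likelihood change
< 1e-8, max 500 iterations (all configurable). The fit is deterministic.

Initialisation: (β, σ², Σ) from a longitudinal-only ML mixed-model fit
(statsmodels MixedLM), γₖ from a no-frailty cause-specific Cox Newton
iteration with νₖ = 0, νₖ = 0, baselines from the Breslow formula at those
values. This is cheap and was inside the basin of attraction in every
simulated configuration exercised by the tests.

## Quadrature

Both rules use a full tensor product of nq Gauss–Hermite nodes per
dimension (physicists' convention), with the e^{|c|²} kernel compensation
folded into log-space accumulation and a log-sum-exp normalisation; all
five moment families for all K risks come from one pass over the grid.

- **Standard rule** (nq = 20 default): nodes √2·Σ^{1/2}c, rescaled to the
  current Σ iterate every EM iteration.
- **Pseudo-adaptive rule** (nq = 6 default, the package default): nodes
  b̃ᵢ + √2·H̃ᵢ^{-1/2}c computed once before the EM loop from the
  preliminary mixed-model fit. b̃ᵢ = ΣZᵢᵀVᵢ⁻¹(Yᵢ−Xᵢβ) with
  Vᵢ = ZᵢΣZᵢᵀ + σ²I, and H̃ᵢ⁻¹ is the Laird–Ware conditional variance of
  the EB estimator including the fixed-effect-estimation correction
  −Vᵢ⁻¹Xᵢ(Σₗ XₗᵀVₗ⁻¹Xₗ)⁻¹XᵢᵀVᵢ⁻¹. The p×p sum in that correction is
  identical for every subject and is computed once and cached, making the
  whole EB pass O(n); symmetric-eigendecomposition square roots are used,
  with a 1e-8 diagonal jitter if an eigenvalue falls below 1e-10.

**Accuracy trade-off, documented deliberately.** With visits on an integer
grid and mean-20 exponential censoring, a minority of subjects accumulate
10–40 longitudinal measurements; their posterior over (b₀, b₁) is one to
two orders of magnitude narrower than the prior. The prior-scaled standard
rule then has essentially no nodes inside the posterior mass: its
per-subject posterior means err by up to ~1 and the error does not shrink
for any practical nq (verified against the exact conjugate closed form at
ν = 0 and against brute-force 2-d integration). Fitted parameters under
the standard rule drift toward the pseudo-adaptive ones as nq grows
(max |difference| ≈ 0.25 at nq = 20, ≈ 0.09 at nq = 40 on one n = 500
dataset) but the two rules are *not* interchangeable at their default node
counts in this design — the reason the pseudo-adaptive rule is the
default, and the reason the standard rule's log-likelihood trace (whose
nodes move with Σ) is not guaranteed monotone, unlike the pseudo-adaptive
trace which ascends to floating-point precision. The pseudo-adaptive
second moments converge more slowly for the data-rich subjects (the EB
variance is deliberately wider than the conditional variance), at worst
~1e-2 at nq = 6; first moments are exact at ν = 0 by symmetry of the
recentred grid.

## Linear scans

All risk-set and step-function work reduces to three primitives over the
globally descending-sorted subject times (sorted once at dataset
construction) and the descending distinct event times of one risk:

1. **step_lookup** — right-continuous step-function evaluation at all
   subject times by a merged forward pass (≤ n + qₖ comparisons);
2. **riskset_suffix_sums** — Σ_{r∈R(tₖⱼ)} a_r for all j by the backward
   recursion R(tₖ₍ⱼ₊₁₎) = R(tₖⱼ) ∪ {r : T_r ∈ [tₖ₍ⱼ₊₁₎, tₖⱼ)}, each
   subject entering the running sum exactly once (vector-valued a_r
   supported, so Hessian blocks are one scan);
3. **event_prefix_map** — B(Tᵢ) with B(t) = Σ_{j: tₖⱼ ≤ t} bₖⱼ, a suffix
   cumulative sum at the event times followed by the same merged lookup.

Each accepts an operation counter; tests assert ≤ 2(n + qₖ) comparisons
and exact agreement (integer inputs) with naive O(n·qₖ) references.
Boundary convention: a subject time equal to an event time takes the value
at that event time (right-continuity of Λ; closed risk sets).

## Standard errors

Ω = (β, vech Σ, σ², γ₁, ν₁, …) is scored per subject from the profiled
likelihood in which the baselines are replaced by the Breslow plug-in
ΔΛₖⱼ = dₖⱼ/S⁰ₖⱼ(γ, ν), holding each subject's posterior law of bᵢ at the
converged fit (so S⁰ is an explicit function of (γ, ν) through
E[e^{νᵀb_r}]). Differentiating that functional gives the E-step terms
plus, for the γₖ/νₖ blocks, the subject's own-event ratio S¹/S⁰ and the
prefix sums B(Tᵢ) with bₖⱼ = dₖⱼS¹ₖⱼ/S⁰ₖⱼ² — computed by scans 2 and 3,
so the n × dim(Ω) score matrix costs O(n·dim Ω). The covariance estimate
inverts Σᵢ sᵢsᵢᵀ (ridge 1e-8 if numerically singular); vech(Σ) uses the
lower triangle row-major with off-diagonal scores doubled. The test suite
certifies every score column against central differences of the same
profiled functional (baseline re-solved at each perturbed Ω) to 1e-4
relative, checks n^{-1/2} SE scaling, and runs a 200-replicate Wald
coverage study for σ².

## Synthetic data

The generator reproduces the study design used throughout: X₁ᵢ ~ N(2, 1),
X₂ᵢ ~ Bernoulli(0.5), bᵢ ~ N₂(0, diag(0.5, 0.25)), σ² = 0.5; constant
baseline hazards 0.05 and 0.1; latent event times by inverse-CDF sampling
of exponentials with subject-specific rates; censoring exponential with
mean 20 (an alternative rate-20 reading would censor everything
immediately and is rejected); visits at t = 0, 1, 2, … up to and including
Tᵢ, with an optional per-visit missingness rate defaulting to 0. The
regression defaults β = (2, −0.5, 1), γ₁ = (0.4, −0.3), γ₂ = (−0.2, 0.3),
ν₁ = (0.5, 0.3), ν₂ = (0.25, −0.25) are moderate values fixed once for the
whole package. What the generator does **not** emulate: irregular or
informative visit schedules, informative censoring, non-Gaussian errors,
time-dependent survival covariates — so passing tests speak to estimator
correctness under the stated design, not to robustness against those
violations.

## Numerical choices and limitations

- Exact floating-point equality detects ties in recorded times; times are
  assumed recorded, not computed.
- Λ(t) = 0 below the smallest jump time; an event subject whose time
  carries no baseline jump is an input error and raises.
- Underflow of every quadrature node for a subject raises with a
  diagnostic rather than returning NaN moments.
- Singular normal equations, zero risk-set denominators, and singular
  Hessians (after a 1e-8 ridge retry) raise; the CLI maps input errors to
  exit code 2 and numerical failures to 3.
- The one-step Newton update can overshoot on tiny datasets; step-halving
  on the expected complete-data objective is a safeguard, not part of the
  estimator at the fixed point.
- SEs for the nonparametric baselines, bootstrap SEs, left truncation,
  interval censoring, time-dependent hazard covariates, and more than one
  longitudinal outcome are out of scope. The scan primitives themselves
  are generic in q and K.
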