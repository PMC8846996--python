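# linjm

Semiparametric joint modelling of a Gaussian longitudinal outcome and a
competing-risks event time, with EM estimation and standard errors whose
per-iteration cost is **linear** in the number of subjects. The package is
aimed at biostatisticians fitting shared-random-effects joint models to
large cohorts (biobank-scale n), where textbook implementations of the same
estimator cost O(n²)–O(n³) per step and become unusable beyond a few
thousand subjects.

## Model

For subject *i* with visit times *t*ᵢⱼ, the longitudinal outcome follows a
linear mixed model and the cause-*k* hazard a proportional cause-specific
hazards model, linked by shared random effects *b*ᵢ:

```
Y_i(t)   = X_i⁽¹⁾(t)ᵀ β + X̃_i⁽¹⁾(t)ᵀ b_i + ε_i(t),      ε ~ N(0, σ²),  b_i ~ N_q(0, Σ)
λ_k(t|·) = λ_0k(t) · exp( X_i⁽²⁾ᵀ γ_k + ν_kᵀ b_i ),      k = 1, …, K
```

with completely unspecified baseline hazards λ₀ₖ(·). Maximum likelihood
runs by EM over the latent *b*ᵢ: the E-step computes per-subject posterior
moments E[bᵢ], E[bᵢbᵢᵀ], E[e^{νₖᵀbᵢ}], E[bᵢe^{νₖᵀbᵢ}], E[bᵢbᵢᵀe^{νₖᵀbᵢ}]
by tensor-product Gauss–Hermite quadrature (standard prior-scaled rule, or
the pseudo-adaptive rule that recentres nodes per subject using empirical
Bayes estimates from a preliminary mixed-model fit); the M-step has closed
forms for β, σ², Σ and the Breslow-type baseline jumps
ΔΛ₀ₖ(t) = dₖⱼ / Σ_{r∈R(t)} e^{γₖᵀX_r}E[e^{νₖᵀb_r}], plus one Newton–Raphson
step for each (γₖ, νₖ). Standard errors come from inverting the empirical
Fisher information Σᵢ ∇l⁽ⁱ⁾∇l⁽ⁱ⁾ᵀ of the baseline-profiled likelihood.

Three scan primitives make every risk-set and step-function evaluation a
single merged pass over descending-sorted times — O(n + qₖ) instead of
O(n·qₖ) or worse: cumulative-hazard lookup at all subject times, suffix
sums Σ_{r∈R(t_kj)} a_r over shrinking risk sets, and the prefix sums
B(Tᵢ) = Σ_{j: t_kj ≤ Tᵢ} b_kj appearing in the profiled scores. Naive
double-loop references for all of them live in `linjm.oracles` and back the
test suite (and `linjm fit --validate`).

## Worked example

`python examples/fit_joint_model.py` simulates n = 500 subjects from the
built-in design (visits at t = 0, 1, 2, …; two competing risks with
constant baseline hazards 0.05 and 0.1; Σ₁₁ = 0.5, Σ₂₂ = 0.25, Σ₁₂ = 0,
σ² = 0.5; exponential censoring with mean 20) and refits them:

```
converged in 29 EM iterations; log-likelihood -5768.99
parameter   estimate      SE   truth
beta_0        1.9196  0.0554    2.00
beta_1       -0.5017  0.0299   -0.50
...
sigma2        0.4948  0.0189    0.50
...
baseline hazard slope, risk 1: 0.0667  (generating constant 0.05)
baseline hazard slope, risk 2: 0.0963  (generating constant 0.1)
```

Estimates sit within about two standard errors of the generating values,
and the fitted step cumulative baseline hazards, divided by t, recover the
generating constants. The other examples show the simulator
(`simulate_dataset.py`), the fast-vs-naive scan agreement and operation
counts (`linear_scan_demo.py`), and why the pseudo-adaptive rule is the
default (`quadrature_rules.py`: with many visits per subject the
prior-scaled standard rule misses narrow posteriors by ~1 regardless of
node count, while the recentred rule is exact to 1e-12 in the
zero-association case).

A thin CLI wraps the same functions:

```
linjm simulate --seed 1 --n 1000 --out-prefix data/sim
linjm fit --long data/sim_long.csv --surv data/sim_surv.csv --out results.json
```

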