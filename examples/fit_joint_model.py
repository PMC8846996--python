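"""Fit the joint model by EM with pseudo-adaptive quadrature and report
estimates with profiled-likelihood standard errors.

The fit alternates an E-step (posterior moments of each subject's random
effects on a fixed, empirically recentred Gauss-Hermite grid) with
closed-form M-step updates and one Newton-Raphson step per risk for the
survival coefficients.  All per-iteration risk-set work is linear in the
number of subjects.
"""

import numpy as np

from linjm import (EMSettings, SimTruth, empirical_fisher, fit, simulate_joint,
                   standard_errors, subject_scores)
from linjm.inference import omega_names, pack_omega

truth = SimTruth(n=500, seed=7)
ds = simulate_joint(truth)
res = fit(ds, EMSettings(quad_mode="pseudo_adaptive", nq=6))
ses = standard_errors(empirical_fisher(subject_scores(ds, res)))

gen = {  # generating values, for side-by-side comparison
    "beta_0": 2.0, "beta_1": -0.5, "beta_2": 1.0,
    "Sigma_00": 0.5, "Sigma_10": 0.0, "Sigma_11": 0.25, "sigma2": 0.5,
    "gamma1_0": 0.4, "gamma1_1": -0.3, "nu1_0": 0.5, "nu1_1": 0.3,
    "gamma2_0": -0.2, "gamma2_1": 0.3, "nu2_0": 0.25, "nu2_1": -0.25,
}
print(f"converged in {res.n_iter} EM iterations; log-likelihood {res.loglik_trace[-1]:.2f}")
print(f"{'parameter':<10} {'estimate':>9} {'SE':>7} {'truth':>7}")
for name, est, se in zip(omega_names(3, 2, 2, 2), pack_omega(res.params), ses):
    print(f"{name:<10} {est:9.4f} {se:7.4f} {gen[name]:7.2f}")
for k, lam in ((1, 0.05), (2, 0.1)):
    slope = res.params.baselines[k - 1].at(5.0) / 5.0
    print(f"baseline hazard slope, risk {k}: {slope:.4f}  (generating constant {lam})")
# Estimates should sit within ~2 SEs of the generating values; the
# baseline slopes recover the constant hazards because the Breslow
# estimator is consistent for the cumulative baseline hazard.
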