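"""Contrast the standard and pseudo-adaptive Gauss-Hermite rules.

The standard rule scales its nodes to the random-effects prior, so a
subject with many longitudinal measurements — whose posterior is far
narrower than the prior — falls between nodes and its posterior moments
are inaccurate no matter the node count within practical limits.  The
pseudo-adaptive rule recentres and rescales nodes per subject using the
preliminary mixed-model fit and resolves the same posterior with 6
nodes per dimension.  The demonstration uses zero association (nu = 0),
where the exact posterior mean is available in closed form.
"""

import numpy as np

from linjm import SimTruth, build_event_index, eb_moments, gh_grid, simulate_joint
from linjm.data_model import ParameterSet, StepCumHazard
from linjm.em_engine import e_step
from linjm.quadrature import pseudo_adaptive_abscissas, standard_abscissas

truth = SimTruth(n=200, seed=8)
ds = simulate_joint(truth)
idx = [build_event_index(ds, k) for k in (1, 2)]
baselines = []
for k, lam in ((1, 0.05), (2, 0.1)):
    t = idx[k - 1].times
    gaps = np.diff(np.concatenate([[0.0], t[::-1]]))
    baselines.append(StepCumHazard(t, (lam * gaps)[::-1].copy()))
params = ParameterSet(beta=truth.beta, sigma2=truth.sigma2, Sigma=truth.Sigma,
                      gamma=[truth.gamma1, truth.gamma2],
                      nu=[np.zeros(2), np.zeros(2)], baselines=baselines)
eb = eb_moments(ds, params.beta, params.sigma2, params.Sigma)  # exact mean at nu=0

n_i = np.diff(ds.row_starts)
print(f"visits per subject: median {int(np.median(n_i))}, max {n_i.max()}")
print(f"{'rule':<16} {'nq':>3} {'max |Eb error|':>15}")
for mode, nq in (("standard", 20), ("standard", 40), ("pseudo-adaptive", 6)):
    g = gh_grid(nq, 2)
    pts = (standard_abscissas(g, params.Sigma) if mode == "standard"
           else pseudo_adaptive_abscissas(g, eb))
    m = e_step(ds, params, pts, g, idx)
    err = np.abs(m.Eb - eb.b_tilde).max()
    print(f"{mode:<16} {nq:>3} {err:15.2e}")
# The pseudo-adaptive error is at floating-point level here because the
# recentred grid puts its central node on the exact posterior mean; the
# prior-scaled rule misses narrow posteriors by a node-spacing amount.
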