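import numpy as np
import pytest

from linjm.data_model import ParameterSet, StepCumHazard, build_event_index
from linjm.em_engine import (EMSettings, e_step, evaluate_baselines, fit,
                             m_step_baseline, m_step_gaussian, m_step_survival,
                             observed_loglik, survival_hessian)
from linjm.lmm_init import eb_moments, lmm_marginal_loglik
from linjm.oracles import naive_hessian
from linjm.quadrature import gh_grid, pseudo_adaptive_abscissas, standard_abscissas
from linjm.simulate import SimTruth, simulate_joint


def _truth_params(ds, nu_zero=False, jumps_scale=1.0):
    t = SimTruth()
    idx = [build_event_index(ds, k) for k in (1, 2)]
    baselines = []
    for k, lam in ((1, 0.05), (2, 0.1)):
        times = idx[k - 1].times
        # constant-hazard increments between consecutive event times
        asc = times[::-1]
        gaps = np.diff(np.concatenate([[0.0], asc]))
        jumps = (lam * gaps * jumps_scale)[::-1].copy()
        baselines.append(StepCumHazard(times, jumps))
    nus = [np.zeros(2), np.zeros(2)] if nu_zero else [t.nu1, t.nu2]
    return ParameterSet(beta=t.beta, sigma2=t.sigma2, Sigma=t.Sigma,
                        gamma=[t.gamma1, t.gamma2], nu=nus, baselines=baselines), idx


@pytest.fixture(scope="module")
def ds100():
    return simulate_joint(SimTruth(n=100, seed=41))


def test_e_step_separability_with_zero_association(ds100):
    """nu = 0 makes the survival factor constant in b: posterior moments
    must equal the pure mixed-model posteriors."""
    params, idx = _truth_params(ds100, nu_zero=True)
    eb = eb_moments(ds100, params.beta, params.sigma2, params.Sigma)
    g = gh_grid(25, 2)
    moments = e_step(ds100, params, pseudo_adaptive_abscissas(g, eb), g, idx)
    # the recentred rule reproduces the Gaussian posterior mean exactly:
    # the transformed integrand is centred, so odd-moment errors vanish
    assert np.allclose(moments.Eb, eb.b_tilde, atol=1e-12)
    assert np.allclose(moments.Eexp, 1.0, rtol=1e-12)

    def max_cov_err(nq):
        g = gh_grid(nq, 2)
        m = e_step(ds100, params, pseudo_adaptive_abscissas(g, eb), g, idx)
        worst = 0.0
        for i in range(ds100.n):
            rows = ds100.subject_rows(i)
            Zi = ds100.Z[rows]
            Vi = Zi @ params.Sigma @ Zi.T + params.sigma2 * np.eye(Zi.shape[0])
            cond = params.Sigma - params.Sigma @ Zi.T @ np.linalg.solve(Vi, Zi @ params.Sigma)
            got = m.Ebb[i] - np.outer(m.Eb[i], m.Eb[i])
            worst = max(worst, np.abs(got - cond).max())
        return worst

    # second moments: accurate at the grid resolution and improving with nq
    # (the EB scale is deliberately wider than the conditional variance for
    # long-follow-up subjects, which slows second-moment convergence)
    e9, e40 = max_cov_err(9), max_cov_err(40)
    assert e9 < 1e-2
    assert e40 < e9 / 2


def test_e_step_matches_brute_force_integration():
    """Per-subject posterior means converge to an exhaustive 2-d grid
    integration of the joint density as the quadrature refines."""
    from linjm.quadrature import _log_prior, log_joint_density

    ds = simulate_joint(SimTruth(n=20, seed=42))
    params, idx = _truth_params(ds)
    eb = eb_moments(ds, params.beta, params.sigma2, params.Sigma)
    Lam_T, log_jump = evaluate_baselines(ds, params, idx)
    # brute-force oracle: normalised Riemann sum over a wide recentred box
    xs = np.linspace(-6, 6, 501)
    box = np.stack(np.meshgrid(xs, xs, indexing="ij"), -1).reshape(-1, 2)
    refs = np.empty((ds.n, 2))
    for i in range(ds.n):
        w_, V_ = np.linalg.eigh(eb.H_inv[i])
        bb = eb.b_tilde[i] + box @ (V_ @ np.diag(np.sqrt(w_)) @ V_.T).T
        lj = log_joint_density(ds.longitudinal[i], ds.survival[i], bb, params,
                               Lam_T[i], log_jump[i]) + _log_prior(bb, params.Sigma)
        w = np.exp(lj - lj.max())
        refs[i] = (w / w.sum()) @ bb

    def worst_err(nq):
        g = gh_grid(nq, 2)
        m = e_step(ds, params, pseudo_adaptive_abscissas(g, eb), g, idx)
        return np.abs(m.Eb - refs).max()

    e6, e25 = worst_err(6), worst_err(25)
    assert e25 < 2e-2
    assert e25 < e6


def test_m_step_gaussian_no_random_effects_is_ols(ds100):
    params, idx = _truth_params(ds100)
    eb = eb_moments(ds100, params.beta, params.sigma2, params.Sigma)
    g = gh_grid(5, 2)
    moments = e_step(ds100, params, pseudo_adaptive_abscissas(g, eb), g, idx)
    moments.Eb[:] = 0.0
    moments.Ebb[:] = 0.0
    beta, sigma2, Sigma = m_step_gaussian(ds100, moments)
    ols = np.linalg.lstsq(ds100.X, ds100.y, rcond=None)[0]
    assert np.allclose(beta, ols, rtol=1e-10)
    assert sigma2 == pytest.approx(np.mean((ds100.y - ds100.X @ ols) ** 2), rel=1e-10)
    assert np.all(Sigma == 0)


def test_m_step_gaussian_sigma_update_averages_moments(ds100):
    params, idx = _truth_params(ds100)
    eb = eb_moments(ds100, params.beta, params.sigma2, params.Sigma)
    g = gh_grid(5, 2)
    moments = e_step(ds100, params, pseudo_adaptive_abscissas(g, eb), g, idx)
    M = np.array([[0.7, 0.1], [0.1, 0.4]])
    moments.Ebb[:] = M
    _, _, Sigma = m_step_gaussian(ds100, moments)
    assert np.allclose(Sigma, M, rtol=1e-14)


def test_m_step_gaussian_is_stationary_point_of_Q(ds100):
    """Finite-difference gradient of the expected complete-data Gaussian
    term vanishes at the closed-form update."""
    params, idx = _truth_params(ds100)
    eb = eb_moments(ds100, params.beta, params.sigma2, params.Sigma)
    g = gh_grid(6, 2)
    moments = e_step(ds100, params, pseudo_adaptive_abscissas(g, eb), g, idx)
    beta, sigma2, Sigma = m_step_gaussian(ds100, moments)

    def Q_gauss(beta_, sigma2_, Sigma_):
        r = ds100.y - ds100.X @ beta_
        zEb = np.sum(ds100.Z * moments.Eb[ds100.obs_subject], axis=1)
        zEbbz = np.einsum("nq,nqr,nr->n", ds100.Z,
                          moments.Ebb[ds100.obs_subject], ds100.Z)
        term_y = np.sum(-0.5 * np.log(2 * np.pi * sigma2_)
                        - (r ** 2 - 2 * r * zEb + zEbbz) / (2 * sigma2_))
        Sinv = np.linalg.inv(Sigma_)
        term_b = -0.5 * ds100.n * np.linalg.slogdet(Sigma_)[1] \
            - 0.5 * np.einsum("nqr,rq->", moments.Ebb, Sinv)
        return term_y + term_b

    f0 = Q_gauss(beta, sigma2, Sigma)
    h = 1e-5
    grads = []
    for j in range(3):
        e = np.zeros(3); e[j] = h
        grads.append((Q_gauss(beta + e, sigma2, Sigma) - Q_gauss(beta - e, sigma2, Sigma)) / (2 * h))
    grads.append((Q_gauss(beta, sigma2 + h, Sigma) - Q_gauss(beta, sigma2 - h, Sigma)) / (2 * h))
    for u in range(2):
        for v in range(u + 1):
            E = np.zeros((2, 2)); E[u, v] = E[v, u] = h
            grads.append((Q_gauss(beta, sigma2, Sigma + E) - Q_gauss(beta, sigma2, Sigma - E)) / (2 * h))
    scale = max(1.0, abs(f0))
    assert np.max(np.abs(grads)) / scale < 1e-6


def test_m_step_baseline_reduces_to_nelson_aalen(ds100):
    params, idx = _truth_params(ds100, nu_zero=True)
    params.gamma = [np.zeros(2), np.zeros(2)]
    eb = eb_moments(ds100, params.beta, params.sigma2, params.Sigma)
    g = gh_grid(6, 2)
    moments = e_step(ds100, params, pseudo_adaptive_abscissas(g, eb), g, idx)
    bl = m_step_baseline(ds100, moments, params.gamma[0], params.nu[0], 1, idx[0])
    for j, t in enumerate(idx[0].times):
        at_risk = np.sum(ds100.surv_time >= t)
        assert bl.jumps[j] == pytest.approx(idx[0].multiplicities[j] / at_risk, rel=1e-12)


def test_m_step_baseline_matches_naive_risk_set_recomputation():
    ds = simulate_joint(SimTruth(n=400, seed=43))
    params, idx = _truth_params(ds)
    eb = eb_moments(ds, params.beta, params.sigma2, params.Sigma)
    g = gh_grid(6, 2)
    moments = e_step(ds, params, pseudo_adaptive_abscissas(g, eb), g, idx)
    for k in (1, 2):
        bl = m_step_baseline(ds, moments, params.gamma[k - 1], params.nu[k - 1], k, idx[k - 1])
        w = np.exp(ds.X2 @ params.gamma[k - 1]) * moments.Eexp[:, k - 1]
        for j, t in enumerate(idx[k - 1].times):
            denom = w[ds.surv_time >= t].sum()
            assert bl.jumps[j] == pytest.approx(idx[k - 1].multiplicities[j] / denom, rel=1e-12)


def test_survival_hessian_matches_naive_double_loop():
    ds = simulate_joint(SimTruth(n=200, seed=44))
    params, idx = _truth_params(ds)
    eb = eb_moments(ds, params.beta, params.sigma2, params.Sigma)
    g = gh_grid(6, 2)
    moments = e_step(ds, params, pseudo_adaptive_abscissas(g, eb), g, idx)
    for k in (1, 2):
        bl = m_step_baseline(ds, moments, params.gamma[k - 1], params.nu[k - 1], k, idx[k - 1])
        H_fast = survival_hessian(ds, moments, params.gamma[k - 1], params.nu[k - 1],
                                  k, idx[k - 1], bl.jumps)
        H_ref = naive_hessian(ds, moments, params.gamma[k - 1], params.nu[k - 1],
                              k, idx[k - 1], bl.jumps)
        assert np.allclose(H_fast, H_ref, rtol=1e-10, atol=1e-12)


def test_m_step_survival_singleton_event():
    ds = simulate_joint(SimTruth(n=1, seed=46))
    if ds.cause[0] == 0:
        pytest.skip("seeded subject is censored")
    k = int(ds.cause[0])
    params, idx = _truth_params(ds)
    g = gh_grid(6, 2)
    moments = e_step(ds, params, standard_abscissas(g, params.Sigma), g, idx)
    bl = m_step_baseline(ds, moments, params.gamma[k - 1], params.nu[k - 1], k, idx[k - 1])
    expected = 1.0 / (np.exp(ds.X2[0] @ params.gamma[k - 1]) * moments.Eexp[0, k - 1])
    assert bl.jumps[0] == pytest.approx(expected, rel=1e-12)


def test_score_vanishes_at_converged_fixed_point(tight_fit30):
    ds, res = tight_fit30
    assert res.converged
    params = res.params
    moments = res.moments
    for k in (1, 2):
        idx = res.event_indices[k - 1]
        bl = m_step_baseline(ds, moments, params.gamma[k - 1], params.nu[k - 1], k, idx)
        g_new, n_new = m_step_survival(ds, moments, params.gamma[k - 1],
                                       params.nu[k - 1], k, idx, bl)
        # at the fixed point one more Newton step moves nothing
        assert np.max(np.abs(g_new - params.gamma[k - 1])) < 1e-6
        assert np.max(np.abs(n_new - params.nu[k - 1])) < 1e-6


def test_observed_loglik_separability_oracle(ds100):
    """With nu = 0 the joint log-likelihood factorises into the mixed-model
    marginal plus the survival log-likelihood, each computable directly."""
    params, idx = _truth_params(ds100, nu_zero=True)
    eb = eb_moments(ds100, params.beta, params.sigma2, params.Sigma)
    ll_lmm = lmm_marginal_loglik(ds100, params.beta, params.sigma2, params.Sigma)
    Lam_T, log_jump = evaluate_baselines(ds100, params, idx)
    ll_surv = 0.0
    for k in (1, 2):
        eta = ds100.X2 @ params.gamma[k - 1]
        ev = ds100.cause == k
        ll_surv += np.sum(log_jump[ev] + eta[ev]) - np.sum(Lam_T[:, k - 1] * np.exp(eta))
    exact = ll_lmm + ll_surv
    errs = []
    for nq in (9, 25, 41):
        g = gh_grid(nq, 2)
        pts = pseudo_adaptive_abscissas(g, eb)
        errs.append(abs(observed_loglik(ds100, params, pts, g, idx) - exact))
    assert errs[1] / abs(exact) < 5e-4   # quadrature-accurate at nq = 25
    assert errs[0] > errs[1] > errs[2]   # and converging as the grid refines


def test_fit_is_deterministic(sim300):
    s = EMSettings(max_iter=8)
    r1 = fit(sim300, s)
    r2 = fit(sim300, s)
    assert r1.loglik_trace == r2.loglik_trace
    assert np.array_equal(r1.params.beta, r2.params.beta)
    assert np.array_equal(r1.params.Sigma, r2.params.Sigma)
    for k in range(2):
        assert np.array_equal(r1.params.nu[k], r2.params.nu[k])
        assert np.array_equal(r1.params.baselines[k].jumps, r2.params.baselines[k].jumps)


def test_fit_ascends_and_recovers_truth(fit300, sim300):
    res = fit300
    assert res.converged
    tr = np.array(res.loglik_trace)
    assert np.all(np.diff(tr) >= -1e-6 * np.abs(tr[:-1]))
    # loose recovery bands at n = 300 (one replicate)
    assert res.params.sigma2 == pytest.approx(0.5, abs=0.12)
    assert res.params.Sigma[0, 0] == pytest.approx(0.5, abs=0.25)
    assert np.allclose(res.params.beta, [2.0, -0.5, 1.0], atol=0.3)


def test_fit_nonconvergence_flag(sim300):
    res = fit(sim300, EMSettings(max_iter=2, tol_param=1e-12, tol_loglik=1e-16))
    assert not res.converged
    assert res.n_iter == 2
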