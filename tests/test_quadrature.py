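import numpy as np
import pytest

from linjm.data_model import ParameterSet, StepCumHazard, SubjectLongitudinal, SubjectSurvival
from linjm.lmm_init import EBEstimates, eb_moments
from linjm.quadrature import (gh_grid, log_joint_density, posterior_moments,
                              pseudo_adaptive_abscissas, standard_abscissas)
from linjm.simulate import SimTruth, simulate_joint


def _params(nu1=(0.5, 0.3), nu2=(0.25, -0.25), jumps1=(0.1,), jumps2=(0.2,)):
    return ParameterSet(
        beta=np.array([2.0, -0.5, 1.0]), sigma2=0.5, Sigma=np.diag([0.5, 0.25]),
        gamma=[np.array([0.4, -0.3]), np.array([-0.2, 0.3])],
        nu=[np.asarray(nu1, float), np.asarray(nu2, float)],
        baselines=[StepCumHazard([1.0], list(jumps1)), StepCumHazard([1.0], list(jumps2))])


# ------------------------------------------------------------------- gh_grid

def test_gh_grid_one_point_rule():
    g = gh_grid(1, 1)
    assert g.abscissas.shape == (1, 1)
    assert g.abscissas[0, 0] == pytest.approx(0.0, abs=1e-15)
    assert g.weights[0] == pytest.approx(np.sqrt(np.pi))


@pytest.mark.parametrize("nq,q", [(2, 1), (5, 1), (3, 2), (6, 2), (4, 3)])
def test_gh_grid_normalization_and_symmetry(nq, q):
    g = gh_grid(nq, q)
    assert g.weights.sum() == pytest.approx(np.pi ** (q / 2.0))
    # grid symmetric under c -> -c: sorted rows of +/- grids coincide
    a = np.sort(g.abscissas.round(12).view([("", float)] * q).ravel())
    b = np.sort((-g.abscissas).round(12).view([("", float)] * q).ravel())
    assert np.array_equal(a, b)


def test_gh_grid_degree3_exactness():
    g = gh_grid(2, 1)
    # integral of c^2 e^{-c^2} = sqrt(pi)/2, exact for a 2-point rule
    assert np.sum(g.weights * g.abscissas[:, 0] ** 2) == pytest.approx(np.sqrt(np.pi) / 2)


# ------------------------------------------------------------------ abscissas

def test_standard_abscissas_identity_and_zero():
    g = gh_grid(4, 1)
    pts = standard_abscissas(g, np.eye(1)).points
    assert np.allclose(pts[:, 0], np.sqrt(2.0) * g.abscissas[:, 0])
    pts0 = standard_abscissas(gh_grid(3, 2), np.zeros((2, 2))).points
    assert np.all(pts0 == 0)


def test_standard_abscissas_diagonal_scaling_oracle():
    g = gh_grid(5, 2)
    Sigma = np.diag([0.5, 0.25])
    pts = standard_abscissas(g, Sigma).points
    ref = np.sqrt(2.0) * g.abscissas * np.sqrt(np.diag(Sigma))
    assert np.allclose(pts, ref, rtol=1e-13)


def test_pseudo_adaptive_reduces_to_standard_normal_case():
    g = gh_grid(3, 2)
    eb = EBEstimates(b_tilde=np.zeros((1, 2)), H_inv=np.eye(2)[None],
                     V_inv_cache=np.eye(3), beta=np.zeros(3), sigma2=1.0,
                     Sigma=np.eye(2))
    pts = pseudo_adaptive_abscissas(g, eb, 0).points
    assert np.allclose(pts, np.sqrt(2.0) * g.abscissas)


def test_pseudo_adaptive_center_node_maps_to_eb_mean():
    g = gh_grid(3, 2)  # odd rule: one node at the origin
    b0 = np.array([1.5, -0.7])
    eb = EBEstimates(b_tilde=b0[None], H_inv=(0.3 * np.eye(2))[None],
                     V_inv_cache=np.eye(3), beta=np.zeros(3), sigma2=1.0,
                     Sigma=np.eye(2))
    pts = pseudo_adaptive_abscissas(g, eb, 0).points
    center = np.where(np.all(np.abs(g.abscissas) < 1e-12, axis=1))[0][0]
    assert np.allclose(pts[center], b0, atol=1e-12)


def test_pseudo_adaptive_matches_matrix_root_oracle():
    rng = np.random.default_rng(0)
    ds = simulate_joint(SimTruth(n=12, seed=31))
    eb = eb_moments(ds, np.array([2.0, -0.5, 1.0]), 0.5, np.diag([0.5, 0.25]))
    g = gh_grid(4, 2)
    all_pts = pseudo_adaptive_abscissas(g, eb).points
    for i in (0, 5, 11):
        w, V = np.linalg.eigh(eb.H_inv[i])
        root = V @ np.diag(np.sqrt(w)) @ V.T
        ref = eb.b_tilde[i] + np.sqrt(2.0) * g.abscissas @ root.T
        assert np.allclose(all_pts[i], ref, rtol=1e-12, atol=1e-14)
        assert np.allclose(pseudo_adaptive_abscissas(g, eb, i).points, ref,
                           rtol=1e-12, atol=1e-14)


# ------------------------------------------------------------- joint density

def test_log_joint_density_scalar_hand_computation():
    lon = SubjectLongitudinal(0, [0.0], [1.2], [[1.0, 0.0, 1.0]], [[1.0, 0.0]])
    sur = SubjectSurvival(0, 1.0, 1, [0.5, 1.0])
    params = _params()
    b = np.array([0.3, -0.1])
    Lam_T = np.array([0.1, 0.2])
    log_jump = np.log(0.1)
    got = log_joint_density(lon, sur, b, params, Lam_T, log_jump)
    # by hand: Gaussian(1.2; 2+1+0.3, 0.5) + event for cause 1 + both cumulative terms
    mean = 2.0 + 1.0 + 0.3
    gauss = -0.5 * np.log(2 * np.pi * 0.5) - (1.2 - mean) ** 2 / 1.0
    eta1 = 0.4 * 0.5 - 0.3 * 1.0 + (0.5 * 0.3 - 0.3 * 0.1)
    eta2 = -0.2 * 0.5 + 0.3 * 1.0 + (0.25 * 0.3 + 0.25 * 0.1)
    ev = np.log(0.1) + eta1
    cum = -0.1 * np.exp(eta1) - 0.2 * np.exp(eta2)
    assert got == pytest.approx(gauss + ev + cum, rel=1e-12)


def test_log_joint_density_event_without_jump_errors():
    lon = SubjectLongitudinal(0, [0.0], [1.2], [[1.0, 0.0, 1.0]], [[1.0, 0.0]])
    sur = SubjectSurvival(0, 1.0, 1, [0.5, 1.0])
    with pytest.raises(ValueError, match="no baseline jump"):
        log_joint_density(lon, sur, np.zeros(2), _params(), np.zeros(2), -np.inf)


# --------------------------------------------------------- posterior moments

def _censored_flat_subject():
    # a censored subject whose longitudinal record is uninformative
    # (huge sigma2 makes the Gaussian factor flat in b)
    lon = SubjectLongitudinal(0, [0.0], [0.0], [[1.0, 0.0, 0.0]], [[1.0, 0.0]])
    sur = SubjectSurvival(0, 0.5, 0, [0.0, 0.0])
    return lon, sur


def test_posterior_weights_self_normalize():
    ds = simulate_joint(SimTruth(n=20, seed=32))
    i = int(np.where(ds.cause == 0)[0][0])  # a censored subject
    params = _params()
    g = gh_grid(5, 2)
    pts = standard_abscissas(g, params.Sigma)
    out = posterior_moments(ds.longitudinal[i], ds.survival[i], params, pts.points,
                            g, np.zeros(2), -np.inf)
    assert out["weights"].sum() == pytest.approx(1.0, rel=1e-12)  # E[1] = 1


def test_prior_recovery_for_uninformative_subject():
    lon, sur = _censored_flat_subject()
    params = _params(nu1=(0.0, 0.0), nu2=(0.0, 0.0))
    params.sigma2 = 1e12
    g = gh_grid(2, 2)  # exact for degree-2 polynomials
    pts = standard_abscissas(g, params.Sigma)
    out = posterior_moments(lon, sur, params, pts.points, g, np.zeros(2), -np.inf)
    assert np.allclose(out["Eb"], 0.0, atol=1e-9)
    assert np.allclose(out["Ebb"], params.Sigma, rtol=1e-9)
    assert np.allclose(out["Eexp"], 1.0, rtol=1e-12)


def test_conjugate_posterior_oracle_with_zero_association():
    """With nu = 0 the posterior of b given the data is the Gaussian
    mixed-model posterior: the quadrature mean must match the closed-form
    EB estimate."""
    ds = simulate_joint(SimTruth(n=20, seed=33))
    params = _params(nu1=(0.0, 0.0), nu2=(0.0, 0.0))
    eb = eb_moments(ds, params.beta, params.sigma2, params.Sigma)
    g = gh_grid(9, 2)
    all_pts = pseudo_adaptive_abscissas(g, eb)
    for i in range(ds.n):
        Lam_T = np.array([bl.at(ds.survival[i].time) for bl in params.baselines])
        log_jump = np.log(0.1)
        out = posterior_moments(ds.longitudinal[i], ds.survival[i], params,
                                all_pts.points[i], g, Lam_T, log_jump)
        # closed-form posterior mean given Y only (survival factor constant in b)
        rows = ds.subject_rows(i)
        Zi, Xi, yi = ds.Z[rows], ds.X[rows], ds.y[rows]
        Vi = Zi @ params.Sigma @ Zi.T + params.sigma2 * np.eye(len(yi))
        ref = params.Sigma @ Zi.T @ np.linalg.solve(Vi, yi - Xi @ params.beta)
        assert np.allclose(out["Eb"], ref, atol=1e-6)


def test_moment_consistency_as_nu_vanishes():
    ds = simulate_joint(SimTruth(n=8, seed=34))
    g = gh_grid(7, 2)
    i = 3
    Lam_T = np.array([0.05, 0.1]) * ds.survival[i].time
    log_jump = np.log(0.05)
    outs = []
    for eps in (1e-3, 1e-5):
        params = _params(nu1=(eps, eps), nu2=(0.0, 0.0))
        pts = standard_abscissas(g, params.Sigma)
        outs.append(posterior_moments(ds.longitudinal[i], ds.survival[i], params,
                                      pts.points, g, Lam_T, log_jump))
    assert outs[-1]["Eexp"][0] == pytest.approx(1.0, abs=1e-4)
    assert np.allclose(outs[-1]["Ebexp"][0], outs[-1]["Eb"], atol=1e-4)


def test_jensen_inequality_for_exp_moment():
    ds = simulate_joint(SimTruth(n=10, seed=35))
    params = _params()
    g = gh_grid(9, 2)
    pts = standard_abscissas(g, params.Sigma)
    for i in range(ds.n):
        Lam_T = np.array([bl.at(ds.survival[i].time) for bl in params.baselines])
        out = posterior_moments(ds.longitudinal[i], ds.survival[i], params,
                                pts.points, g, Lam_T, np.log(0.1))
        for k in range(2):
            assert out["Eexp"][k] >= np.exp(params.nu[k] @ out["Eb"]) - 1e-12
        cov = out["Ebb"] - np.outer(out["Eb"], out["Eb"])
        assert np.linalg.eigvalsh(cov).min() > -1e-10
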