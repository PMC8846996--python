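"""Tensor-product Gauss–Hermite quadrature and E-step posterior moments.

The E-step needs, per subject, ratios of integrals of the form

    E[h(b_i)] = ∫ h(b) f(Y_i, C_i | b) f(b | Σ) db / ∫ f(Y_i, C_i | b) f(b | Σ) db.

Both integrals are approximated on the same tensor-product
Gauss–Hermite grid after one of two changes of variable:

* standard rule:        b̃_t = √2 Σ^{1/2} c_t (recomputed every EM
  iteration, since it depends on the current Σ);
* pseudo-adaptive rule: r̃_t = b̃_i + √2 H̃_i^{−1/2} c_t, centred on the
  empirical Bayes estimates from the preliminary mixed-model fit and
  computed once before the EM loop.

The Gaussian kernel of the rule is compensated by an exp(|c_t|²) factor
folded into log-space accumulation; all densities are evaluated on the
log scale with a log-sum-exp normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial.hermite import hermgauss
from scipy.special import logsumexp

from .data_model import JointDataset, ParameterSet, SubjectLongitudinal, SubjectSurvival
from .lmm_init import EBEstimates, _sym_sqrt

__all__ = [
    "QuadratureGrid", "GridPoints", "PosteriorMoments",
    "gh_grid", "standard_abscissas", "pseudo_adaptive_abscissas",
    "log_joint_density", "posterior_moments", "batch_posterior_moments",
]


@dataclass
class QuadratureGrid:
    """Tensor product of 1-d Gauss–Hermite nodes (physicists' convention:
    weight e^{−x²}, Σ weights = √π per dimension)."""

    nq: int
    q: int
    abscissas: np.ndarray  # (G, q) with G = nq**q
    weights: np.ndarray    # (G,)

    @property
    def n_points(self) -> int:
        return int(self.weights.shape[0])

    @property
    def log_comp_weights(self) -> np.ndarray:
        """log π_t + |c_t|², the weight with the Gaussian kernel removed."""
        return np.log(self.weights) + np.sum(self.abscissas ** 2, axis=1)


@dataclass
class GridPoints:
    """Rescaled abscissas at which the joint density is evaluated.

    ``points`` is (n, G, q) for the pseudo-adaptive rule (per subject) or
    (G, q) for the standard rule (shared).  ``log_jacobian`` is the log
    volume element of the change of variable — ``(q/2)·log 2 + ½ log|Σ|``
    for the standard rule, per-subject ``(q/2)·log 2 + ½ log|H̃_i⁻¹|``
    for the pseudo-adaptive rule — needed only for the observed
    log-likelihood (it cancels in moment ratios).
    """

    points: np.ndarray
    log_jacobian: np.ndarray | float
    mode: str  # "standard" | "pseudo_adaptive"

    def for_subject(self, i: int) -> np.ndarray:
        return self.points if self.points.ndim == 2 else self.points[i]


@dataclass
class PosteriorMoments:
    """E-step expectations for all subjects at the current parameters.

    Shapes: Eb (n, q); Ebb (n, q, q); per risk k: Eexp (n, K),
    Ebexp (n, K, q), Ebbexp (n, K, q, q).  ``log_norm`` is the log of
    the quadrature sum normalising each subject's posterior (the
    observed log-likelihood contribution up to the Jacobian), and
    ``weights`` the normalised grid weights, kept so that expectations
    of new functions of b (e.g. e^{νᵀb} at a trial ν during
    step-halving) can be formed without re-evaluating the density.
    """

    Eb: np.ndarray
    Ebb: np.ndarray
    Eexp: np.ndarray
    Ebexp: np.ndarray
    Ebbexp: np.ndarray
    log_norm: np.ndarray
    weights: np.ndarray = field(repr=False)  # (n, G)
    points: GridPoints = field(repr=False)

    def exp_nu(self, k_nu: np.ndarray) -> np.ndarray:
        """E[exp(νᵀ b_i)] for an arbitrary ν under the stored posterior."""
        P = self.points.points
        if P.ndim == 2:
            s = P @ k_nu  # (G,)
            return self.weights @ np.exp(s)
        s = np.einsum("ngq,q->ng", P, k_nu)
        return np.sum(self.weights * np.exp(s), axis=1)


def gh_grid(nq: int, q: int) -> QuadratureGrid:
    """Full tensor-product Gauss–Hermite grid: nq nodes per dimension."""
    if nq < 1 or q < 1:
        raise ValueError("nq and q must be >= 1")
    x, w = hermgauss(nq)
    grids = np.meshgrid(*([x] * q), indexing="ij")
    abscissas = np.stack([g.ravel() for g in grids], axis=1)
    wgrids = np.meshgrid(*([w] * q), indexing="ij")
    weights = np.prod(np.stack([g.ravel() for g in wgrids], axis=1), axis=1)
    return QuadratureGrid(nq=nq, q=q, abscissas=abscissas, weights=weights)


def standard_abscissas(grid: QuadratureGrid, Sigma: np.ndarray) -> GridPoints:
    """Standard rescaling b̃_t = √2 Σ^{1/2} c_t (depends on the current Σ,
    so it is recomputed at every EM iteration)."""
    Sigma = np.asarray(Sigma, dtype=float)
    w = np.linalg.eigvalsh(0.5 * (Sigma + Sigma.T))
    if w.min() < -1e-10:
        raise ValueError("Sigma must be positive semi-definite")
    root = _psd_sqrt(Sigma)
    pts = np.sqrt(2.0) * grid.abscissas @ root.T
    sign, logdet = np.linalg.slogdet(Sigma) if w.min() > 0 else (0, -np.inf)
    log_jac = 0.5 * grid.q * np.log(2.0) + 0.5 * logdet
    return GridPoints(points=pts, log_jacobian=log_jac, mode="standard")


def _psd_sqrt(M: np.ndarray) -> np.ndarray:
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def pseudo_adaptive_abscissas(grid: QuadratureGrid, eb: EBEstimates,
                              i: int | None = None) -> GridPoints:
    """Pseudo-adaptive rescaling r̃_t = b̃_i + √2 H̃_i^{−1/2} c_t.

    With ``i`` given, returns the (G, q) points of one subject; without,
    the (n, G, q) points of every subject.  These are computed once
    before the EM loop and never updated.
    """
    roots = eb.H_inv_sqrt
    logdet = eb.log_det_H_inv
    if i is not None:
        pts = eb.b_tilde[i] + np.sqrt(2.0) * grid.abscissas @ roots[i].T
        log_jac = 0.5 * grid.q * np.log(2.0) + 0.5 * logdet[i]
        return GridPoints(points=pts, log_jacobian=log_jac, mode="pseudo_adaptive")
    pts = eb.b_tilde[:, None, :] + np.sqrt(2.0) * np.einsum("gq,nrq->ngr", grid.abscissas, roots)
    log_jac = 0.5 * grid.q * np.log(2.0) + 0.5 * logdet
    return GridPoints(points=pts, log_jacobian=log_jac, mode="pseudo_adaptive")


def log_joint_density(lon: SubjectLongitudinal, sur: SubjectSurvival,
                      b: np.ndarray, params: ParameterSet,
                      Lam_T: np.ndarray, log_jump: float) -> np.ndarray:
    """log f(Y_i, C_i | b, Ψ) at one or many values of b.

    ``b`` is (q,) or (G, q).  ``Lam_T`` holds Λ_0k(T_i) for k = 1..K and
    ``log_jump`` the log jump of the observed cause's baseline at T_i
    (ignored for censored subjects) — both are evaluated beforehand by
    the linear hazard lookup.  Entirely on the log scale:
    Gaussian longitudinal part + event-term + cumulative-hazard term.
    """
    b2 = np.atleast_2d(np.asarray(b, dtype=float))  # (G, q)
    out = np.zeros(b2.shape[0])
    if lon.n_obs > 0:
        mean_fixed = lon.fixed_design @ params.beta
        u = lon.random_design @ b2.T  # (n_i, G)
        resid = (lon.responses - mean_fixed)[:, None] - u
        out += np.sum(-0.5 * np.log(2 * np.pi * params.sigma2)
                      - resid ** 2 / (2 * params.sigma2), axis=0)
    for k in range(params.K):
        eta = float(sur.covariates @ params.gamma[k])
        nub = b2 @ params.nu[k]
        out -= Lam_T[k] * np.exp(eta + nub)
        if sur.cause == k + 1:
            if not np.isfinite(log_jump):
                raise ValueError(
                    f"subject {sur.subject_id!r}: event at T={sur.time} carries no baseline jump")
            out += log_jump + eta + nub
    return out if np.asarray(b).ndim > 1 else float(out[0])


def _log_prior(b2: np.ndarray, Sigma: np.ndarray) -> np.ndarray:
    """log N_q(b; 0, Σ) rows of b2 (…, q)."""
    q = Sigma.shape[0]
    sign, logdet = np.linalg.slogdet(Sigma)
    sol = np.linalg.solve(Sigma, b2.reshape(-1, q).T).T.reshape(b2.shape)
    quad = np.sum(b2 * sol, axis=-1)
    return -0.5 * (q * np.log(2 * np.pi) + logdet + quad)


def posterior_moments(lon: SubjectLongitudinal, sur: SubjectSurvival,
                      params: ParameterSet, points: np.ndarray,
                      grid: QuadratureGrid, Lam_T: np.ndarray,
                      log_jump: float) -> dict:
    """Single-subject posterior moments (self-normalised ratio estimator).

    Returns a dict with keys Eb, Ebb, Eexp, Ebexp, Ebbexp, log_norm,
    weights.  The log integrand is log π_t + |c_t|² + log f(Y,C|b_t)
    + log f(b_t|Σ); the maximum is subtracted before exponentiating.
    """
    pts = np.asarray(points, dtype=float)  # (G, q)
    logint = (grid.log_comp_weights
              + log_joint_density(lon, sur, pts, params, Lam_T, log_jump)
              + _log_prior(pts, params.Sigma))
    m = logint.max()
    if not np.isfinite(m):
        raise FloatingPointError(
            f"subject {sur.subject_id!r}: all quadrature integrand values underflowed")
    log_norm = m + np.log(np.sum(np.exp(logint - m)))
    wt = np.exp(logint - log_norm)
    Eb = wt @ pts
    Ebb = np.einsum("g,gq,gr->qr", wt, pts, pts)
    K = params.K
    q = grid.q
    Eexp = np.empty(K)
    Ebexp = np.empty((K, q))
    Ebbexp = np.empty((K, q, q))
    for k in range(K):
        e = np.exp(pts @ params.nu[k])
        Eexp[k] = wt @ e
        Ebexp[k] = (wt * e) @ pts
        Ebbexp[k] = np.einsum("g,gq,gr->qr", wt * e, pts, pts)
    return dict(Eb=Eb, Ebb=Ebb, Eexp=Eexp, Ebexp=Ebexp, Ebbexp=Ebbexp,
                log_norm=float(log_norm), weights=wt)


def batch_posterior_moments(dataset: JointDataset, params: ParameterSet,
                            grid_points: GridPoints, grid: QuadratureGrid,
                            Lam_T: np.ndarray, log_jump: np.ndarray) -> PosteriorMoments:
    """Vectorised E-step over all subjects.

    ``Lam_T`` is (n, K) with Λ_0k(T_i); ``log_jump`` (n,) with
    log ΔΛ_{0,D_i}(T_i) for event subjects (any value for censored).
    All five moment families for all K risks come from a single pass
    over the grid.  Cost O(n · nq^q).
    """
    n, q, K = dataset.n, dataset.q, params.K
    P = grid_points.points
    per_subject = P.ndim == 3
    G = grid.n_points

    # longitudinal log-density accumulated per subject
    resid = dataset.y - dataset.X @ params.beta  # (N,)
    if per_subject:
        u = np.einsum("nq,ngq->ng", dataset.Z, P[dataset.obs_subject])
    else:
        u = dataset.Z @ P.T  # (N, G)
    obs_ll = -0.5 * np.log(2 * np.pi * params.sigma2) - (resid[:, None] - u) ** 2 / (2 * params.sigma2)
    loglong = np.add.reduceat(obs_ll, dataset.row_starts[:-1], axis=0)  # (n, G)
    # subjects with zero longitudinal rows cannot occur (n_i >= 1 enforced)

    # survival log-density and the exp(nu'b) factors, reused for the moments
    Pn = P if per_subject else np.broadcast_to(P, (n, G, q))
    logsurv = np.zeros((n, G))
    nub = np.empty((K, n, G))
    for k in range(K):
        eta = dataset.X2 @ params.gamma[k]  # (n,)
        nub[k] = np.einsum("ngq,q->ng", Pn, params.nu[k])
        logsurv -= Lam_T[:, k][:, None] * np.exp(eta[:, None] + nub[k])
        ev = dataset.cause == k + 1
        if np.any(ev):
            if not np.all(np.isfinite(log_jump[ev])):
                bad = np.where(ev & ~np.isfinite(log_jump))[0][0]
                raise ValueError(
                    f"subject index {bad}: event time carries no baseline jump")
            logsurv[ev] += (log_jump[ev] + eta[ev])[:, None] + nub[k][ev]

    logprior = _log_prior(Pn, params.Sigma)  # (n, G)
    logint = grid.log_comp_weights[None, :] + loglong + logsurv + logprior
    m = logint.max(axis=1)
    if not np.all(np.isfinite(m)):
        bad = np.where(~np.isfinite(m))[0][0]
        raise FloatingPointError(
            f"subject index {bad}: all quadrature integrand values underflowed")
    log_norm = logsumexp(logint, axis=1)
    wt = np.exp(logint - log_norm[:, None])  # (n, G)

    Eb = np.einsum("ng,ngq->nq", wt, Pn)
    Ebb = np.einsum("ng,ngq,ngr->nqr", wt, Pn, Pn)
    Eexp = np.empty((n, K))
    Ebexp = np.empty((n, K, q))
    Ebbexp = np.empty((n, K, q, q))
    for k in range(K):
        e = np.exp(nub[k])  # (n, G)
        we = wt * e
        Eexp[:, k] = we.sum(axis=1)
        Ebexp[:, k] = np.einsum("ng,ngq->nq", we, Pn)
        Ebbexp[:, k] = np.einsum("ng,ngq,ngr->nqr", we, Pn, Pn)
    return PosteriorMoments(Eb=Eb, Ebb=Ebb, Eexp=Eexp, Ebexp=Ebexp, Ebbexp=Ebbexp,
                            log_norm=log_norm, weights=wt, points=grid_points)
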