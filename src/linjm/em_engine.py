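"""EM estimation of the semiparametric joint model.

The E-step computes per-subject posterior moments of the shared random
effects by Gauss–Hermite quadrature (standard or pseudo-adaptive rule).
The M-step has closed forms for (β, σ², Σ) and for the Breslow-type
baseline hazard jumps, and performs one Newton–Raphson step (with
step-halving) for each (γ_k, ν_k).  Every per-iteration quantity that
aggregates over risk sets or evaluates step baseline hazards goes
through the linear scans of :mod:`linjm.hazard_scan`, so one EM
iteration costs O(n · nq^q) with no quadratic term in n.

Block structure of one iteration (a generalised EM): each M-step block
weakly increases the expected complete-data log-likelihood Q, so the
observed log-likelihood trace is nondecreasing up to quadrature noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .data_model import (EventTimeIndex, JointDataset, ParameterSet,
                         StepCumHazard, build_event_index)
from .hazard_scan import event_prefix_map, riskset_suffix_sums, step_lookup
from .lmm_init import EBEstimates, eb_moments, fit_lmm
from .quadrature import (GridPoints, PosteriorMoments, batch_posterior_moments,
                         gh_grid, pseudo_adaptive_abscissas, standard_abscissas)

__all__ = ["EMSettings", "FitResult", "e_step", "m_step_gaussian",
           "m_step_baseline", "m_step_survival", "survival_hessian",
           "observed_loglik", "evaluate_baselines", "fit"]

logger = logging.getLogger(__name__)


@dataclass
class EMSettings:
    """Tuning knobs of the EM loop.

    ``quad_mode`` selects the quadrature rule ("pseudo_adaptive",
    default nq=6, or "standard", default nq=20).  Convergence is
    declared when the max relative parameter change drops below
    ``tol_param`` or the relative log-likelihood change below
    ``tol_loglik``.  ``fix_nu`` pins every ν_k at 0, reducing the
    survival submodel to cause-specific Cox regression.
    """

    quad_mode: str = "pseudo_adaptive"
    nq: int | None = None
    tol_param: float = 1e-4
    tol_loglik: float = 1e-8
    max_iter: int = 500
    fix_nu: bool = False
    nr_halvings: int = 10

    def __post_init__(self) -> None:
        if self.quad_mode not in ("pseudo_adaptive", "standard"):
            raise ValueError("quad_mode must be 'pseudo_adaptive' or 'standard'")
        if self.nq is None:
            self.nq = 6 if self.quad_mode == "pseudo_adaptive" else 20


@dataclass
class FitResult:
    """Converged parameters plus the objects needed for inference."""

    params: ParameterSet
    loglik_trace: list
    n_iter: int
    converged: bool
    settings: EMSettings
    moments: PosteriorMoments = field(repr=False)
    grid: object = field(repr=False)
    grid_points: GridPoints = field(repr=False)
    eb: EBEstimates | None = field(default=None, repr=False)
    event_indices: list = field(default=None, repr=False)


def evaluate_baselines(dataset: JointDataset, params: ParameterSet,
                       event_indices: list) -> tuple[np.ndarray, np.ndarray]:
    """Λ_0k(T_i) for all subjects and risks, and log ΔΛ at each event.

    Uses the merged forward scan over the descending subject times and
    the descending baseline jump times — O(n + q_k) per risk.  Returns
    ``Lam_T`` (n, K) and ``log_jump`` (n,) with −inf for censored
    subjects (never consumed).
    """
    ord_ = dataset.desc_order
    sorted_times = dataset.surv_time[ord_]
    n, K = dataset.n, params.K
    Lam_T = np.zeros((n, K))
    log_jump = np.full(n, -np.inf)
    for k in range(K):
        bl = params.baselines[k]
        if bl.jump_times.size:
            vals_sorted = step_lookup(bl.cum_values, bl.jump_times, sorted_times)
            Lam_T[ord_, k] = vals_sorted
        idx = event_indices[k]
        ev = dataset.cause == k + 1
        if np.any(ev):
            if bl.jump_times.size != idx.times.size or (
                    bl.jump_times.size and not np.array_equal(bl.jump_times, idx.times)):
                raise ValueError(f"baseline jump times for risk {k + 1} do not match the "
                                 "dataset's event times")
            with np.errstate(divide="ignore"):
                log_jump[ev] = np.log(bl.jumps[idx.subject_event_j[ev]])
    return Lam_T, log_jump


def e_step(dataset: JointDataset, params: ParameterSet, grid_points: GridPoints,
           grid, event_indices: list) -> PosteriorMoments:
    """Posterior moments of b_i for every subject at the current Ψ."""
    Lam_T, log_jump = evaluate_baselines(dataset, params, event_indices)
    return batch_posterior_moments(dataset, params, grid_points, grid, Lam_T, log_jump)


def m_step_gaussian(dataset: JointDataset, moments: PosteriorMoments,
                    XtX: np.ndarray | None = None) -> tuple[np.ndarray, float, np.ndarray]:
    """Closed-form updates of (β, σ², Σ) from the E-step moments."""
    X, Z, y = dataset.X, dataset.Z, dataset.y
    if XtX is None:
        XtX = X.T @ X
    Eb_rows = moments.Eb[dataset.obs_subject]        # (N, q)
    zEb = np.sum(Z * Eb_rows, axis=1)                # (N,)
    try:
        beta = np.linalg.solve(XtX, X.T @ (y - zEb))
    except np.linalg.LinAlgError as err:
        raise ValueError("singular normal equations for beta") from err
    r = y - X @ beta
    Ebb_rows = moments.Ebb[dataset.obs_subject]      # (N, q, q)
    zEbbz = np.einsum("nq,nqr,nr->n", Z, Ebb_rows, Z)
    sigma2 = float(np.mean(r ** 2 - 2 * r * zEb + zEbbz))
    Sigma = moments.Ebb.mean(axis=0)
    Sigma = 0.5 * (Sigma + Sigma.T)
    return beta, sigma2, Sigma


def m_step_baseline(dataset: JointDataset, moments: PosteriorMoments,
                    gamma_k: np.ndarray, nu_k: np.ndarray, k: int,
                    event_index: EventTimeIndex,
                    counter: dict | None = None) -> StepCumHazard:
    """Breslow-type baseline update for risk ``k`` (1-based).

    ΔΛ_0k(t_kj) = d_kj / Σ_{r ∈ R(t_kj)} exp(X_r⁽²⁾ᵀ γ_k) E[exp(ν_kᵀ b_r)],
    with the risk-set denominators from the linear suffix-sum scan.
    """
    ord_ = dataset.desc_order
    sorted_times = dataset.surv_time[ord_]
    w = np.exp(dataset.X2 @ gamma_k) * moments.Eexp[:, k - 1]
    S0 = riskset_suffix_sums(w[ord_], event_index.times, sorted_times, counter=counter)
    if np.any(S0 <= 0):
        raise ZeroDivisionError(f"zero risk-set denominator for risk {k}")
    jumps = event_index.multiplicities / S0
    return StepCumHazard(jump_times=event_index.times.copy(), jumps=jumps)


def survival_hessian(dataset: JointDataset, moments: PosteriorMoments,
                     gamma_k: np.ndarray, nu_k: np.ndarray, k: int,
                     event_index: EventTimeIndex, jumps: np.ndarray,
                     counter: dict | None = None) -> np.ndarray:
    """Expected-information matrix for the stacked (γ_k, ν_k).

    Blockwise Σ_j ΔΛ_kj Σ_{r∈R(t_kj)} exp(X_rᵀγ_k)·{E[e^{νᵀb}] X Xᵀ,
    E[b e^{νᵀb}] Xᵀ, E[bbᵀ e^{νᵀb}]}, each risk-set aggregate produced by
    one linear suffix-sum scan.
    """
    ord_ = dataset.desc_order
    sorted_times = dataset.surv_time[ord_]
    p2, q = dataset.p2, dataset.q
    eg = np.exp(dataset.X2 @ gamma_k)
    kk = k - 1
    a_gg = (eg * moments.Eexp[:, kk])[:, None, None] * \
        np.einsum("np,nr->npr", dataset.X2, dataset.X2)          # (n, p2, p2)
    a_gn = eg[:, None, None] * np.einsum("nq,np->nqp", moments.Ebexp[:, kk], dataset.X2)
    a_nn = eg[:, None, None] * moments.Ebbexp[:, kk]             # (n, q, q)
    stacked = np.concatenate([a_gg.reshape(dataset.n, -1),
                              a_gn.reshape(dataset.n, -1),
                              a_nn.reshape(dataset.n, -1)], axis=1)
    sums = riskset_suffix_sums(stacked[ord_], event_index.times, sorted_times,
                               counter=counter)                  # (q_k, d)
    agg = jumps @ sums if jumps.size else np.zeros(stacked.shape[1])
    H = np.zeros((p2 + q, p2 + q))
    H[:p2, :p2] = agg[:p2 * p2].reshape(p2, p2)
    gn = agg[p2 * p2:p2 * p2 + q * p2].reshape(q, p2)
    H[p2:, :p2] = gn
    H[:p2, p2:] = gn.T
    H[p2:, p2:] = agg[p2 * p2 + q * p2:].reshape(q, q)
    return H


def _survival_Q(dataset: JointDataset, moments: PosteriorMoments, k: int,
                gamma_k: np.ndarray, nu_k: np.ndarray, Lam_T_k: np.ndarray) -> float:
    """Expected complete-data objective for (γ_k, ν_k), baseline fixed.

    E[exp(νᵀb)] at the trial ν is formed from the stored posterior grid
    weights, so step-halving can compare objectives exactly."""
    eta = dataset.X2 @ gamma_k
    ev = dataset.cause == k
    term_ev = np.sum(eta[ev] + moments.Eb[ev] @ nu_k)
    expnu = moments.exp_nu(nu_k)
    return float(term_ev - np.sum(Lam_T_k * np.exp(eta) * expnu))


def m_step_survival(dataset: JointDataset, moments: PosteriorMoments,
                    gamma_k: np.ndarray, nu_k: np.ndarray, k: int,
                    event_index: EventTimeIndex, baseline: StepCumHazard,
                    fix_nu: bool = False, n_halvings: int = 10,
                    counter: dict | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One Newton–Raphson step on the stacked (γ_k, ν_k).

    The score and expected information use risk-set aggregates from the
    linear scans; the freshly updated baseline stays fixed during the
    step.  The increment is halved (up to ``n_halvings`` times) whenever
    the expected complete-data objective would decrease.
    """
    ord_ = dataset.desc_order
    sorted_times = dataset.surv_time[ord_]
    p2, q = dataset.p2, dataset.q
    kk = k - 1
    ev = dataset.cause == k
    eg = np.exp(dataset.X2 @ gamma_k)

    # risk-set sums S1 (covariates) and S1b (b-moments) for the score
    a = np.concatenate([(eg * moments.Eexp[:, kk])[:, None] * dataset.X2,
                        eg[:, None] * moments.Ebexp[:, kk]], axis=1)  # (n, p2+q)
    S = riskset_suffix_sums(a[ord_], event_index.times, sorted_times, counter=counter)
    d = event_index.multiplicities
    U_gamma = dataset.X2[ev].sum(axis=0) - (baseline.jumps[:, None] * S[:, :p2]).sum(axis=0)
    U_nu = moments.Eb[ev].sum(axis=0) - (baseline.jumps[:, None] * S[:, p2:]).sum(axis=0)
    H = survival_hessian(dataset, moments, gamma_k, nu_k, k, event_index,
                         baseline.jumps, counter=counter)

    if fix_nu:
        U = U_gamma
        Hm = H[:p2, :p2]
    else:
        U = np.concatenate([U_gamma, U_nu])
        Hm = H
    try:
        step = np.linalg.solve(Hm, U)
    except np.linalg.LinAlgError:
        Hm = Hm + 1e-8 * np.eye(Hm.shape[0])
        try:
            step = np.linalg.solve(Hm, U)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular Hessian for risk {k} after ridge fallback") from err

    Lam_T_k = _lambda_at_subjects(dataset, baseline)
    Q_old = _survival_Q(dataset, moments, k, gamma_k, nu_k, Lam_T_k)
    scale = 1.0
    for _ in range(n_halvings + 1):
        g_new = gamma_k + scale * step[:p2]
        n_new = nu_k if fix_nu else nu_k + scale * step[p2:]
        if _survival_Q(dataset, moments, k, g_new, n_new, Lam_T_k) >= Q_old:
            return g_new, n_new
        scale *= 0.5
    logger.debug("risk %d: Newton step rejected after %d halvings", k, n_halvings)
    return gamma_k, nu_k


def _lambda_at_subjects(dataset: JointDataset, baseline: StepCumHazard) -> np.ndarray:
    ord_ = dataset.desc_order
    sorted_times = dataset.surv_time[ord_]
    out = np.zeros(dataset.n)
    if baseline.jump_times.size:
        out[ord_] = step_lookup(baseline.cum_values, baseline.jump_times, sorted_times)
    return out


def observed_loglik(dataset: JointDataset, params: ParameterSet,
                    grid_points: GridPoints, grid,
                    event_indices: list | None = None) -> float:
    """Quadrature approximation of the observed-data log-likelihood."""
    if dataset.n == 0:
        return 0.0
    if event_indices is None:
        event_indices = [build_event_index(dataset, k + 1) for k in range(params.K)]
    moments = e_step(dataset, params, grid_points, grid, event_indices)
    return _loglik_from_moments(moments, grid_points, dataset.n)


def _loglik_from_moments(moments: PosteriorMoments, grid_points: GridPoints, n: int) -> float:
    jac = grid_points.log_jacobian
    jac_total = float(np.sum(jac)) if np.ndim(jac) else n * float(jac)
    return float(np.sum(moments.log_norm) + jac_total)


def _cox_gamma_init(dataset: JointDataset, k: int, event_index: EventTimeIndex,
                    max_iter: int = 25, tol: float = 1e-9) -> tuple[np.ndarray, StepCumHazard]:
    """No-frailty cause-specific Cox fit (Breslow ties) by Newton iterations
    on the profile score — cheap starting values for γ_k."""
    ord_ = dataset.desc_order
    sorted_times = dataset.surv_time[ord_]
    p2 = dataset.p2
    gamma = np.zeros(p2)
    ev = dataset.cause == k
    d = event_index.multiplicities
    if event_index.q_k == 0:
        return gamma, StepCumHazard(event_index.times.copy(), np.zeros(0))
    for _ in range(max_iter):
        w = np.exp(dataset.X2 @ gamma)
        XX = np.einsum("np,nr->npr", dataset.X2, dataset.X2).reshape(dataset.n, -1)
        a = np.concatenate([w[:, None], w[:, None] * dataset.X2, w[:, None] * XX], axis=1)
        S = riskset_suffix_sums(a[ord_], event_index.times, sorted_times)
        S0, S1 = S[:, 0], S[:, 1:1 + p2]
        S2 = S[:, 1 + p2:].reshape(-1, p2, p2)
        U = dataset.X2[ev].sum(axis=0) - (d[:, None] * S1 / S0[:, None]).sum(axis=0)
        ratio = S1 / S0[:, None]
        H = np.einsum("j,jpr->pr", d, S2 / S0[:, None, None]) - \
            np.einsum("j,jp,jr->pr", d, ratio, ratio)
        try:
            step = np.linalg.solve(H + 1e-10 * np.eye(p2), U)
        except np.linalg.LinAlgError:
            break
        gamma = gamma + step
        if np.max(np.abs(step)) < tol:
            break
    w = np.exp(dataset.X2 @ gamma)
    S0 = riskset_suffix_sums(w[ord_], event_index.times, sorted_times)
    return gamma, StepCumHazard(event_index.times.copy(), d / S0)


def fit(dataset: JointDataset, settings: EMSettings | None = None,
        init: tuple | None = None) -> FitResult:
    """Fit the joint model by the EM algorithm.

    Initialisation: (β, σ², Σ) from the longitudinal-only mixed-model
    fit (or ``init``), γ_k from a no-frailty cause-specific Cox fit,
    ν_k = 0, baselines from the Breslow formula at those values.  The
    fit is deterministic: identical inputs give identical results.
    """
    settings = settings or EMSettings()
    if init is not None:
        beta, sigma2, Sigma = init
        beta = np.asarray(beta, dtype=float)
        Sigma = np.asarray(Sigma, dtype=float)
    else:
        beta, sigma2, Sigma = fit_lmm(dataset)

    grid = gh_grid(settings.nq, dataset.q)
    eb = None
    if settings.quad_mode == "pseudo_adaptive":
        eb = eb_moments(dataset, beta, sigma2, Sigma)
        grid_points = pseudo_adaptive_abscissas(grid, eb)
    else:
        grid_points = standard_abscissas(grid, Sigma)

    K = dataset.K
    event_indices = [build_event_index(dataset, k + 1) for k in range(K)]
    gamma, baselines = [], []
    for k in range(K):
        g, bl = _cox_gamma_init(dataset, k + 1, event_indices[k])
        gamma.append(g)
        baselines.append(bl)
    nu = [np.zeros(dataset.q) for _ in range(K)]
    params = ParameterSet(beta=beta, sigma2=sigma2, Sigma=Sigma,
                          gamma=gamma, nu=nu, baselines=baselines)

    XtX = dataset.X.T @ dataset.X
    trace: list[float] = []
    converged = False
    moments = None
    for it in range(settings.max_iter):
        if settings.quad_mode == "standard":
            grid_points = standard_abscissas(grid, params.Sigma)
        moments = e_step(dataset, params, grid_points, grid, event_indices)
        ll = _loglik_from_moments(moments, grid_points, dataset.n)
        trace.append(ll)

        new = params.copy()
        new.beta, new.sigma2, new.Sigma = m_step_gaussian(dataset, moments, XtX)
        for k in range(1, K + 1):
            bl = m_step_baseline(dataset, moments, params.gamma[k - 1],
                                 params.nu[k - 1], k, event_indices[k - 1])
            g_new, n_new = m_step_survival(
                dataset, moments, params.gamma[k - 1], params.nu[k - 1], k,
                event_indices[k - 1], bl, fix_nu=settings.fix_nu,
                n_halvings=settings.nr_halvings)
            new.gamma[k - 1], new.nu[k - 1] = g_new, n_new
            new.baselines[k - 1] = bl

        delta = _param_change(params, new)
        ll_change = abs(trace[-1] - trace[-2]) / (abs(trace[-2]) + 1e-10) if it > 0 else np.inf
        params = new
        if delta < settings.tol_param or ll_change < settings.tol_loglik:
            converged = True
            break

    if settings.quad_mode == "standard":
        grid_points = standard_abscissas(grid, params.Sigma)
    moments = e_step(dataset, params, grid_points, grid, event_indices)
    trace.append(_loglik_from_moments(moments, grid_points, dataset.n))
    logger.info("EM finished: %d iterations, converged=%s, loglik=%.6f",
                len(trace) - 1, converged, trace[-1])
    return FitResult(params=params, loglik_trace=trace, n_iter=len(trace) - 1,
                     converged=converged, settings=settings, moments=moments,
                     grid=grid, grid_points=grid_points, eb=eb,
                     event_indices=event_indices)


def _param_change(old: ParameterSet, new: ParameterSet) -> float:
    parts = [
        (old.beta, new.beta),
        (np.array([old.sigma2]), np.array([new.sigma2])),
        (old.Sigma.ravel(), new.Sigma.ravel()),
    ]
    for g0, g1 in zip(old.gamma, new.gamma):
        parts.append((g0, g1))
    for v0, v1 in zip(old.nu, new.nu):
        parts.append((v0, v1))
    return max(float(np.max(np.abs(b - a) / (np.abs(a) + 1e-4))) if a.size else 0.0
               for a, b in parts)
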