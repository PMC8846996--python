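"""Standard errors from the profiled-likelihood empirical Fisher information.

The parametric component Ω = (β, vech Σ, σ², γ_1, ν_1, …, γ_K, ν_K) is
scored per subject after profiling out the nonparametric baselines with
the Breslow plug-in ΔΛ_kj = d_kj / S0_kj(γ_k, ν_k), where

    S0_kj = Σ_{r ∈ R(t_kj)} exp(γ_kᵀ X_r⁽²⁾) E[exp(ν_kᵀ b_r)]

and the per-subject posterior law of b_r is held at the converged fit.
Differentiating that functional gives, besides the usual E-step terms,
prefix-sum corrections B(T_i) = Σ_{j: t_kj ≤ T_i} b_kj with

    b_kj = d_kj · S1_kj / S0_kj²   (S1 with X_r⁽²⁾ or the b-moments),

which the linear scans of :mod:`linjm.hazard_scan` produce in O(n + q_k),
so the whole n × dim(Ω) score matrix costs O(n · dim(Ω)).

Column order of Ω (documented for the JSON output): β (p entries),
vech(Σ) lower triangle row-major ((0,0), (1,0), (1,1), …), σ², then for
each risk k = 1..K: γ_k (p2 entries) followed by ν_k (q entries).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data_model import JointDataset, ParameterSet, StepCumHazard
from .em_engine import FitResult, evaluate_baselines
from .hazard_scan import event_prefix_map, riskset_suffix_sums, step_lookup
from .quadrature import batch_posterior_moments

__all__ = ["ScoreMatrix", "subject_scores", "empirical_fisher", "standard_errors",
           "omega_names", "pack_omega", "unpack_omega", "profiled_loglik_subjects"]


@dataclass
class ScoreMatrix:
    """Per-subject profiled-likelihood scores (n rows, dim(Ω) columns)."""

    matrix: np.ndarray
    column_names: list

    @property
    def dim(self) -> int:
        return self.matrix.shape[1]


def _vech_indices(q: int) -> list:
    return [(u, v) for u in range(q) for v in range(u + 1)]


def omega_names(p: int, q: int, p2: int, K: int) -> list:
    names = [f"beta_{j}" for j in range(p)]
    names += [f"Sigma_{u}{v}" for u, v in _vech_indices(q)]
    names += ["sigma2"]
    for k in range(1, K + 1):
        names += [f"gamma{k}_{j}" for j in range(p2)]
        names += [f"nu{k}_{j}" for j in range(q)]
    return names


def pack_omega(params: ParameterSet) -> np.ndarray:
    """Flatten the parametric component into the documented column order."""
    q = params.Sigma.shape[0]
    parts = [params.beta,
             np.array([params.Sigma[u, v] for u, v in _vech_indices(q)]),
             np.array([params.sigma2])]
    for g, v in zip(params.gamma, params.nu):
        parts += [g, v]
    return np.concatenate(parts)


def unpack_omega(vec: np.ndarray, template: ParameterSet) -> ParameterSet:
    """Rebuild a ParameterSet from a packed Ω (baselines copied from the
    template; they are re-profiled by the caller)."""
    vec = np.asarray(vec, dtype=float)
    p = template.beta.shape[0]
    q = template.Sigma.shape[0]
    beta = vec[:p]
    pos = p
    Sigma = np.zeros((q, q))
    for u, v in _vech_indices(q):
        Sigma[u, v] = Sigma[v, u] = vec[pos]
        pos += 1
    sigma2 = vec[pos]
    pos += 1
    gamma, nu = [], []
    for k in range(template.K):
        p2 = template.gamma[k].shape[0]
        gamma.append(vec[pos:pos + p2]); pos += p2
        nu.append(vec[pos:pos + q]); pos += q
    return ParameterSet(beta=beta, sigma2=sigma2, Sigma=Sigma, gamma=gamma,
                        nu=nu, baselines=[StepCumHazard(b.jump_times.copy(), b.jumps.copy())
                                          for b in template.baselines])


def _profile_baselines(dataset: JointDataset, fit: FitResult,
                       gamma: list, nu: list) -> list:
    """Breslow plug-in baselines at (γ, ν) with the posterior law of each
    b_r frozen at the converged fit."""
    ord_ = dataset.desc_order
    sorted_times = dataset.surv_time[ord_]
    out = []
    for k, idx in enumerate(fit.event_indices):
        w = np.exp(dataset.X2 @ gamma[k]) * fit.moments.exp_nu(nu[k])
        S0 = riskset_suffix_sums(w[ord_], idx.times, sorted_times)
        if np.any(S0 <= 0):
            raise ZeroDivisionError(f"zero risk-set denominator for risk {k + 1}")
        out.append(StepCumHazard(idx.times.copy(), idx.multiplicities / S0))
    return out


def profiled_loglik_subjects(dataset: JointDataset, fit: FitResult,
                             omega: np.ndarray) -> np.ndarray:
    """Per-subject profiled log-likelihood l⁽ⁱ⁾(Ω) at an arbitrary Ω.

    The baselines are re-solved by the frozen-posterior Breslow plug-in
    at the perturbed (γ, ν); the integral over b uses the fit's fixed
    quadrature points.  This is the functional whose analytic gradient
    :func:`subject_scores` computes, and the target of the
    finite-difference certification in the test-suite.
    """
    params = unpack_omega(omega, fit.params)
    params.baselines = _profile_baselines(dataset, fit, params.gamma, params.nu)
    Lam_T, log_jump = evaluate_baselines(dataset, params, fit.event_indices)
    moments = batch_posterior_moments(dataset, params, fit.grid_points, fit.grid,
                                      Lam_T, log_jump)
    jac = fit.grid_points.log_jacobian
    jac = np.full(dataset.n, float(jac)) if np.ndim(jac) == 0 else np.asarray(jac)
    return moments.log_norm + jac


def subject_scores(dataset: JointDataset, fit: FitResult) -> ScoreMatrix:
    """Analytic per-subject profiled scores at the converged fit.

    Refuses non-converged fits.  The γ_k/ν_k blocks combine (i) the
    subject's own event/cumulative-hazard terms, (ii) the ratio
    S1_{kj(i)}/S0_{kj(i)} at the subject's own event time, and (iii) the
    prefix sums B(T_i) computed by the linear event-prefix scan.
    """
    if not fit.converged:
        raise ValueError("fit did not converge; refusing to compute standard errors")
    params = fit.params
    moments = fit.moments
    n, p, q, p2, K = dataset.n, dataset.p, dataset.q, dataset.p2, params.K
    ord_ = dataset.desc_order
    sorted_times = dataset.surv_time[ord_]
    names = omega_names(p, q, p2, K)
    S = np.zeros((n, len(names)))

    # --- beta block: Σ_j x_ij (r_ij − z_ijᵀ E[b_i]) / σ²
    r = dataset.y - dataset.X @ params.beta
    zEb = np.sum(dataset.Z * moments.Eb[dataset.obs_subject], axis=1)
    rows_beta = dataset.X * ((r - zEb) / params.sigma2)[:, None]
    np.add.at(S[:, :p], dataset.obs_subject, rows_beta)

    # --- vech(Sigma) block: ½(Σ⁻¹ E[bbᵀ] Σ⁻¹ − Σ⁻¹), off-diagonals doubled
    Sig_inv = np.linalg.inv(params.Sigma)
    G = 0.5 * (np.einsum("uv,nvw,wx->nux", Sig_inv, moments.Ebb, Sig_inv) - Sig_inv[None])
    pos = p
    for u, v in _vech_indices(q):
        S[:, pos] = G[:, u, v] if u == v else 2.0 * G[:, u, v]
        pos += 1

    # --- sigma2 block
    zEbbz = np.einsum("nq,nqr,nr->n", dataset.Z,
                      moments.Ebb[dataset.obs_subject], dataset.Z)
    per_obs = (-0.5 / params.sigma2
               + (r ** 2 - 2 * r * zEb + zEbbz) / (2 * params.sigma2 ** 2))
    np.add.at(S[:, pos], dataset.obs_subject, per_obs)
    pos += 1

    # --- survival blocks per risk
    for k in range(1, K + 1):
        kk = k - 1
        idx = fit.event_indices[kk]
        ev = dataset.cause == k
        eg = np.exp(dataset.X2 @ params.gamma[kk])
        w = eg * moments.Eexp[:, kk]                       # (n,)
        wb = eg[:, None] * moments.Ebexp[:, kk]            # (n, q)
        stacked = np.concatenate([w[:, None], w[:, None] * dataset.X2, wb], axis=1)
        sums = riskset_suffix_sums(stacked[ord_], idx.times, sorted_times)
        S0 = sums[:, 0]
        S1 = sums[:, 1:1 + p2]
        S1b = sums[:, 1 + p2:]
        d = idx.multiplicities
        if idx.q_k and np.any(S0 <= 0):
            raise ZeroDivisionError(f"zero risk-set denominator for risk {k}")
        jumps = d / S0 if idx.q_k else np.zeros(0)
        # Λ_k(T_i) under the self-consistent Breslow plug-in
        Lam = np.zeros(n)
        if idx.q_k:
            cum = jumps[::-1].cumsum()[::-1]
            Lam[ord_] = step_lookup(cum, idx.times, sorted_times)
        # prefix-sum corrections B(T_i)
        if idx.q_k:
            b_gamma = (d / S0 ** 2)[:, None] * S1          # (q_k, p2)
            b_nu = (d / S0 ** 2)[:, None] * S1b            # (q_k, q)
            Bg = np.zeros((n, p2)); Bn = np.zeros((n, q))
            Bg[ord_] = event_prefix_map(b_gamma, idx.times, sorted_times)
            Bn[ord_] = event_prefix_map(b_nu, idx.times, sorted_times)
        else:
            Bg = np.zeros((n, p2)); Bn = np.zeros((n, q))

        sc_gamma = (np.where(ev, 1.0, 0.0) - Lam * w)[:, None] * dataset.X2 \
            + w[:, None] * Bg
        sc_nu = np.where(ev, 1.0, 0.0)[:, None] * moments.Eb - Lam[:, None] * wb \
            + w[:, None] * Bn
        if idx.q_k:
            j_of = idx.subject_event_j
            has = j_of >= 0
            sc_gamma[has] -= S1[j_of[has]] / S0[j_of[has], None]
            sc_nu[has] -= S1b[j_of[has]] / S0[j_of[has], None]
        S[:, pos:pos + p2] = sc_gamma
        pos += p2
        S[:, pos:pos + q] = sc_nu
        pos += q

    return ScoreMatrix(matrix=S, column_names=names)


def empirical_fisher(scores: ScoreMatrix) -> np.ndarray:
    """Σ_i s_i s_iᵀ — symmetric PSD by construction."""
    M = scores.matrix
    if not np.all(np.isfinite(M)):
        raise ValueError("score matrix contains non-finite entries")
    F = M.T @ M
    return 0.5 * (F + F.T)


def standard_errors(fisher: np.ndarray) -> np.ndarray:
    """Square roots of the diagonal of the inverse information.

    A ridge of 1e-8 (scaled by the mean diagonal) is added if the matrix
    is numerically singular."""
    try:
        cov = np.linalg.inv(fisher)
    except np.linalg.LinAlgError:
        ridge = 1e-8 * max(np.mean(np.diag(fisher)), 1.0)
        cov = np.linalg.inv(fisher + ridge * np.eye(fisher.shape[0]))
    diag = np.diag(cov)
    if np.any(diag < 0):
        ridge = 1e-8 * max(np.mean(np.diag(fisher)), 1.0)
        cov = np.linalg.inv(fisher + ridge * np.eye(fisher.shape[0]))
        diag = np.diag(cov)
    return np.sqrt(np.clip(diag, 0.0, None))
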