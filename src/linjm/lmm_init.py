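"""Longitudinal-only mixed-model fit and empirical Bayes quantities.

The pseudo-adaptive quadrature rule needs, before the EM loop starts,
the empirical Bayes (EB) estimates of each subject's random effects and
their conditional covariance from a preliminary linear mixed model fit:

    b̃_i   = Σ Z_iᵀ V_i⁻¹ (Y_i − X_i β),          V_i = Z_i Σ Z_iᵀ + σ² I,
    H̃_i⁻¹ = Σ − Σ Z_iᵀ [V_i⁻¹ − V_i⁻¹ X_i (Σ_l X_lᵀ V_l⁻¹ X_l)⁻¹ X_iᵀ V_i⁻¹] Z_i Σ,

the Laird–Ware conditional variance that accounts for estimating β.
The p×p sum Σ_l X_lᵀ V_l⁻¹ X_l appears in every H̃_i⁻¹; computing it
once and reusing the cached value makes the whole pass O(n) in the
number of subjects rather than O(n²).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import JointDataset

__all__ = ["EBEstimates", "fit_lmm", "eb_moments", "lmm_marginal_loglik"]

logger = logging.getLogger(__name__)

_EIG_FLOOR = 1e-10
_JITTER = 1e-8


@dataclass
class EBEstimates:
    """Per-subject EB means/covariances plus the shared p×p cache."""

    b_tilde: np.ndarray    # (n, q)
    H_inv: np.ndarray      # (n, q, q)
    V_inv_cache: np.ndarray  # (p, p): Σ_l X_lᵀ V_l⁻¹ X_l
    beta: np.ndarray
    sigma2: float
    Sigma: np.ndarray

    @property
    def H_inv_sqrt(self) -> np.ndarray:
        """Symmetric matrix square roots of the H̃_i⁻¹ (n, q, q)."""
        roots = np.empty_like(self.H_inv)
        for i in range(self.H_inv.shape[0]):
            roots[i] = _sym_sqrt(self.H_inv[i])
        return roots

    @property
    def log_det_H_inv(self) -> np.ndarray:
        """log|H̃_i⁻¹| per subject (Jacobians of the adaptive rescaling)."""
        return np.array([np.linalg.slogdet(H)[1] for H in self.H_inv])


def _sym_sqrt(M: np.ndarray) -> np.ndarray:
    """Symmetric PSD square root via eigendecomposition, with jitter for
    near-singular matrices."""
    M = 0.5 * (M + M.T)
    w, V = np.linalg.eigh(M)
    if w.min() < _EIG_FLOOR:
        logger.warning("near-singular matrix in square root (min eig %.3g); adding jitter", w.min())
        M = M + _JITTER * np.eye(M.shape[0])
        w, V = np.linalg.eigh(M)
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def fit_lmm(dataset: JointDataset) -> tuple[np.ndarray, float, np.ndarray]:
    """Maximum-likelihood fit of the longitudinal submodel alone.

    Returns (beta, sigma2, Sigma) for the marginal linear mixed model
    Y_i ~ N(X_i β, Z_i Σ Z_iᵀ + σ² I).  The fit is by ML (not REML)
    since it seeds a joint maximum-likelihood procedure.
    """
    n_params = dataset.p + dataset.q * (dataset.q + 1) // 2 + 1
    if dataset.n_total_obs <= n_params:
        raise ValueError("too few longitudinal observations to fit the mixed model")
    import statsmodels.api as sm

    groups = dataset.obs_subject
    model = sm.MixedLM(dataset.y, dataset.X, groups=groups, exog_re=dataset.Z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = model.fit(reml=False, method="lbfgs", maxiter=400)
            if not np.all(np.isfinite(res.fe_params)):
                raise ValueError("non-finite fixed effects")
        except Exception:
            res = model.fit(reml=False, maxiter=400)
    beta = np.asarray(res.fe_params, dtype=float)
    sigma2 = float(res.scale)
    Sigma = np.asarray(res.cov_re, dtype=float) * 1.0
    # guard: MixedLM can return a boundary (singular) Sigma
    w = np.linalg.eigvalsh(0.5 * (Sigma + Sigma.T))
    if w.min() < 1e-8:
        Sigma = Sigma + (1e-8 - min(w.min(), 0.0) + 1e-10) * np.eye(dataset.q)
    logger.info("LMM init: beta=%s sigma2=%.6g Sigma diag=%s", beta, sigma2, np.diag(Sigma))
    return beta, sigma2, Sigma


def lmm_marginal_loglik(dataset: JointDataset, beta: np.ndarray, sigma2: float,
                        Sigma: np.ndarray) -> float:
    """Direct evaluation of the Gaussian marginal log-likelihood
    Σ_i log N(Y_i; X_i β, Z_i Σ Z_iᵀ + σ² I) — used as an independent
    check on any inner optimizer."""
    total = 0.0
    for i in range(dataset.n):
        rows = dataset.subject_rows(i)
        Xi, Zi, yi = dataset.X[rows], dataset.Z[rows], dataset.y[rows]
        Vi = Zi @ Sigma @ Zi.T + sigma2 * np.eye(len(yi))
        r = yi - Xi @ beta
        sign, logdet = np.linalg.slogdet(Vi)
        total += -0.5 * (len(yi) * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(Vi, r))
    return float(total)


def eb_moments(dataset: JointDataset, beta: np.ndarray, sigma2: float,
               Sigma: np.ndarray) -> EBEstimates:
    """Empirical Bayes means b̃_i and conditional covariances H̃_i⁻¹.

    The shared sum Σ_l X_lᵀ V_l⁻¹ X_l is accumulated once and cached, so
    the total cost is linear in the number of subjects (per-subject cost
    depends only on n_i, p, q).
    """
    beta = np.asarray(beta, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    n, p, q = dataset.n, dataset.p, dataset.q

    # first pass: per-subject solves and the shared p×p cache
    Vinv_X = []      # V_i⁻¹ X_i
    Vinv_Z = []      # V_i⁻¹ Z_i
    resid = []       # Y_i − X_i β
    cache = np.zeros((p, p))
    b_tilde = np.empty((n, q))
    for i in range(n):
        rows = dataset.subject_rows(i)
        Xi, Zi, yi = dataset.X[rows], dataset.Z[rows], dataset.y[rows]
        Vi = Zi @ Sigma @ Zi.T + sigma2 * np.eye(len(yi))
        try:
            Vi_chol = np.linalg.cholesky(Vi)
        except np.linalg.LinAlgError as err:
            raise ValueError(f"singular V_i for subject index {i}") from err
        sol = np.linalg.solve(Vi_chol.T, np.linalg.solve(Vi_chol, np.column_stack([Xi, Zi])))
        ViX, ViZ = sol[:, :p], sol[:, p:]
        ri = yi - Xi @ beta
        cache += Xi.T @ ViX
        b_tilde[i] = Sigma @ (ViZ.T @ ri)
        Vinv_X.append(ViX)
        Vinv_Z.append(ViZ)
        resid.append(ri)

    cache_inv = np.linalg.inv(cache)
    # second pass: H̃_i⁻¹ using the cached p×p sum
    H_inv = np.empty((n, q, q))
    for i in range(n):
        rows = dataset.subject_rows(i)
        Xi, Zi = dataset.X[rows], dataset.Z[rows]
        ViZ, ViX = Vinv_Z[i], Vinv_X[i]
        inner = ViZ.T @ Zi  # Z_iᵀ V_i⁻¹ Z_i
        corr = (ViX.T @ Zi).T @ cache_inv @ (ViX.T @ Zi)  # Z_iᵀV⁻¹X (ΣXᵀV⁻¹X)⁻¹ XᵀV⁻¹Z
        Hi = Sigma - Sigma @ (inner - corr) @ Sigma
        H_inv[i] = 0.5 * (Hi + Hi.T)
    return EBEstimates(b_tilde=b_tilde, H_inv=H_inv, V_inv_cache=cache,
                       beta=beta, sigma2=float(sigma2), Sigma=Sigma)
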