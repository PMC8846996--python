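"""Synthetic joint longitudinal / competing-risks data generator.

Emulates the simulation design used throughout the test suite: a
random-intercept/random-slope Gaussian outcome

    Y_ij = β0 + β1 t_ij + β2 X2_i + b0_i + b1_i t_ij + ε_ij,

with scheduled visits t_ij = 0, 1, 2, ..., and two competing event
times drawn from constant-baseline proportional cause-specific hazards

    λ_k(t) = λ_0k exp(γ_k1 X1_i + γ_k2 X2_i + ν_kᵀ b_i),   k = 1, 2,

where X1_i ~ N(2, 1), X2_i ~ Bernoulli(0.5), b_i ~ N2(0, Σ).
Censoring is an independent exponential; the observed time is the
minimum of the two latent event times and censoring, and longitudinal
visits after the observed time are dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .data_model import JointDataset, SubjectLongitudinal, SubjectSurvival

__all__ = ["SimTruth", "simulate_joint", "simulate_replicates"]


@dataclass
class SimTruth:
    """Generating parameters of the synthetic joint model.

    Defaults: variance components Σ₁₁ = 0.5, Σ₂₂ = 0.25, Σ₁₂ = 0,
    σ² = 0.5, constant baseline hazards λ₀₁ = 0.05 and λ₀₂ = 0.1, and
    exponential censoring with mean 20.  The regression coefficients
    are moderate values chosen once for the whole package.
    """

    beta: np.ndarray = field(default_factory=lambda: np.array([2.0, -0.5, 1.0]))
    Sigma: np.ndarray = field(default_factory=lambda: np.array([[0.5, 0.0], [0.0, 0.25]]))
    sigma2: float = 0.5
    gamma1: np.ndarray = field(default_factory=lambda: np.array([0.4, -0.3]))
    gamma2: np.ndarray = field(default_factory=lambda: np.array([-0.2, 0.3]))
    nu1: np.ndarray = field(default_factory=lambda: np.array([0.5, 0.3]))
    nu2: np.ndarray = field(default_factory=lambda: np.array([0.25, -0.25]))
    lambda01: float = 0.05
    lambda02: float = 0.1
    censor_mean: float = 20.0
    n: int = 500
    seed: int = 0
    visit_missing_rate: float = 0.0  # per-visit missingness after baseline

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        for name in ("gamma1", "gamma2", "nu1", "nu2"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.lambda01 <= 0 or self.lambda02 <= 0:
            raise ValueError("baseline hazards must be > 0")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.censor_mean <= 0:
            raise ValueError("censor_mean must be > 0")
        w = np.linalg.eigvalsh(0.5 * (self.Sigma + self.Sigma.T))
        if w.min() < -1e-12:
            raise ValueError("Sigma must be positive semi-definite")
        if not (0.0 <= self.visit_missing_rate < 1.0):
            raise ValueError("visit_missing_rate must be in [0, 1)")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v) for k, v in d.items()}

    @classmethod
    def from_dict(cls, d: dict) -> "SimTruth":
        return cls(**d)


def simulate_joint(truth: SimTruth) -> JointDataset:
    """Draw one joint dataset under ``truth``.

    Latent cause-specific event times come from the inverse CDF of an
    exponential with subject-specific rate λ₀ₖ·exp(γₖᵀXᵢ + νₖᵀbᵢ); the
    observed time is the minimum of the two event times and the
    censoring time, with the cause recording the argmin (0 = censored).
    """
    rng = np.random.default_rng(truth.seed)
    n = truth.n
    x1 = rng.normal(2.0, 1.0, size=n)
    x2 = rng.binomial(1, 0.5, size=n).astype(float)
    # PSD-safe square root of Sigma for degenerate cases
    w, V = np.linalg.eigh(0.5 * (truth.Sigma + truth.Sigma.T))
    root = V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T
    b = rng.standard_normal((n, 2)) @ root.T

    X2cov = np.column_stack([x1, x2])
    rate1 = truth.lambda01 * np.exp(X2cov @ truth.gamma1 + b @ truth.nu1)
    rate2 = truth.lambda02 * np.exp(X2cov @ truth.gamma2 + b @ truth.nu2)
    u1, u2 = rng.random(n), rng.random(n)
    t1 = -np.log(u1) / rate1
    t2 = -np.log(u2) / rate2
    cens = rng.exponential(truth.censor_mean, size=n)

    times = np.column_stack([cens, t1, t2])
    cause = np.argmin(times, axis=1)  # 0 = censored, 1, 2 = causes
    T = times[np.arange(n), cause]

    sigma = np.sqrt(truth.sigma2)
    longitudinal, survival = [], []
    for i in range(n):
        visits = np.arange(0.0, np.floor(T[i]) + 1.0)
        if truth.visit_missing_rate > 0 and visits.size > 1:
            keep = rng.random(visits.size - 1) >= truth.visit_missing_rate
            visits = np.concatenate([visits[:1], visits[1:][keep]])
        m = visits.size
        fixed = np.column_stack([np.ones(m), visits, np.full(m, x2[i])])
        rand = np.column_stack([np.ones(m), visits])
        mean = fixed @ truth.beta + rand @ b[i]
        y = mean + sigma * rng.standard_normal(m)
        sid = i
        longitudinal.append(SubjectLongitudinal(
            subject_id=sid, times=visits, responses=y,
            fixed_design=fixed, random_design=rand))
        survival.append(SubjectSurvival(
            subject_id=sid, time=T[i], cause=int(cause[i]),
            covariates=np.array([x1[i], x2[i]])))

    ds = JointDataset(longitudinal=longitudinal, survival=survival,
                      n=n, p=3, q=2, K=2, p2=2)
    ds.true_random_effects = b  # kept for recovery checks in tests
    return ds


def simulate_replicates(truth: SimTruth, R: int) -> list:
    """R independent datasets with seeds seed, seed+1, ..., seed+R−1."""
    if R < 1:
        raise ValueError("R must be >= 1")
    out = []
    for r in range(R):
        d = truth.to_dict()
        d["seed"] = truth.seed + r
        out.append(simulate_joint(SimTruth.from_dict(d)))
    return out
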