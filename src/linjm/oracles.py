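"""Deliberately naive reference implementations of every scan.

Each function here reproduces the contract of a linear-scan primitive
by global search or nested loops — O(n·q_k), O(n²) or worse — and
exists only to certify the fast algorithms on small instances (the test
suite, and the CLI ``--validate`` flag).  Performance is a non-goal.
"""

from __future__ import annotations

import numpy as np

from .data_model import EventTimeIndex, JointDataset
from .quadrature import PosteriorMoments

__all__ = ["naive_step_lookup", "naive_riskset_sums", "naive_event_prefix",
           "naive_hessian", "naive_score_B_terms"]


def naive_step_lookup(values_at_event_times: np.ndarray, event_times: np.ndarray,
                      sorted_times: np.ndarray, counter: dict | None = None) -> np.ndarray:
    """Per-subject global search over all event times."""
    vals = np.asarray(values_at_event_times, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    sorted_times = np.asarray(sorted_times, dtype=float)
    n, q_k = sorted_times.shape[0], event_times.shape[0]
    out = np.zeros((n,) if vals.ndim == 1 else (n, vals.shape[1]))
    for i in range(n):
        for j in range(q_k):
            if counter is not None:
                counter["comparisons"] = counter.get("comparisons", 0) + 1
            if sorted_times[i] >= event_times[j]:
                out[i] = vals[j]
                break
    return out


def naive_riskset_sums(a: np.ndarray, event_times: np.ndarray,
                       sorted_times: np.ndarray, counter: dict | None = None) -> np.ndarray:
    """Re-scan every subject for every event time."""
    a = np.asarray(a, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    sorted_times = np.asarray(sorted_times, dtype=float)
    q_k = event_times.shape[0]
    d = None if a.ndim == 1 else a.shape[1]
    out = np.zeros((q_k,) if d is None else (q_k, d))
    for j in range(q_k):
        total = 0.0 if d is None else np.zeros(d)
        for i in range(sorted_times.shape[0]):
            if counter is not None:
                counter["comparisons"] = counter.get("comparisons", 0) + 1
            if sorted_times[i] >= event_times[j]:
                total = total + a[i]
        out[j] = total
    return out


def naive_event_prefix(b_kj: np.ndarray, event_times: np.ndarray,
                       sorted_times: np.ndarray, counter: dict | None = None) -> np.ndarray:
    """Double loop over subjects × event times for B(T_i) = Σ_{t_kj ≤ T_i} b_kj."""
    b_kj = np.asarray(b_kj, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    sorted_times = np.asarray(sorted_times, dtype=float)
    n, q_k = sorted_times.shape[0], event_times.shape[0]
    out = np.zeros((n,) if b_kj.ndim == 1 else (n, b_kj.shape[1]))
    for i in range(n):
        for j in range(q_k):
            if counter is not None:
                counter["comparisons"] = counter.get("comparisons", 0) + 1
            if event_times[j] <= sorted_times[i]:
                out[i] = out[i] + b_kj[j]
    return out


def naive_hessian(dataset: JointDataset, moments: PosteriorMoments,
                  gamma_k: np.ndarray, nu_k: np.ndarray, k: int,
                  event_index: EventTimeIndex, jumps: np.ndarray) -> np.ndarray:
    """Expected information for (γ_k, ν_k) by explicit risk-set recomputation."""
    p2, q = dataset.p2, dataset.q
    kk = k - 1
    eg = np.exp(dataset.X2 @ gamma_k)
    H = np.zeros((p2 + q, p2 + q))
    for j in range(event_index.q_k):
        t = event_index.times[j]
        block = np.zeros((p2 + q, p2 + q))
        for r in range(dataset.n):
            if dataset.surv_time[r] >= t:
                x = dataset.X2[r]
                block[:p2, :p2] += eg[r] * moments.Eexp[r, kk] * np.outer(x, x)
                block[p2:, :p2] += eg[r] * np.outer(moments.Ebexp[r, kk], x)
                block[p2:, p2:] += eg[r] * moments.Ebbexp[r, kk]
        block[:p2, p2:] = block[p2:, :p2].T
        H += jumps[j] * block
    return H


def naive_score_B_terms(dataset: JointDataset, moments: PosteriorMoments,
                        gamma_k: np.ndarray, k: int,
                        event_index: EventTimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """B(T_i) prefix sums of the profiled score by a full double loop.

    Returns (B_gamma (n, p2), B_nu (n, q)) in original subject order.
    """
    p2, q = dataset.p2, dataset.q
    kk = k - 1
    eg = np.exp(dataset.X2 @ gamma_k)
    w = eg * moments.Eexp[:, kk]
    wb = eg[:, None] * moments.Ebexp[:, kk]
    Bg = np.zeros((dataset.n, p2))
    Bn = np.zeros((dataset.n, q))
    for j in range(event_index.q_k):
        t = event_index.times[j]
        in_risk = dataset.surv_time >= t
        S0 = w[in_risk].sum()
        S1 = (w[in_risk, None] * dataset.X2[in_risk]).sum(axis=0)
        S1b = wb[in_risk].sum(axis=0)
        d = event_index.multiplicities[j]
        bg = d * S1 / S0 ** 2
        bn = d * S1b / S0 ** 2
        reaches = dataset.surv_time >= t  # t_kj <= T_i
        Bg[reaches] += bg
        Bn[reaches] += bn
    return Bg, Bn
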