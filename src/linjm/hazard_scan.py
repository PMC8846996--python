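"""Linear-time scan primitives over descending-sorted survival times.

Three pure functions, each a single merged pass over the subject times
(descending) and the distinct event times of one risk (descending):

* :func:`step_lookup` — evaluate a right-continuous step function with
  known values at the event times at every subject time (cumulative
  baseline hazard lookup).
* :func:`riskset_suffix_sums` — risk-set aggregates Σ_{r ∈ R(t_kj)} a_r
  for all event times, exploiting that risk sets only shrink in time.
* :func:`event_prefix_map` — B(T_i) where B(t) = Σ_{j: t_kj ≤ t} b_kj,
  the prefix-sum terms of the profiled score.

Each does O(n + q_k) comparisons; an optional ``counter`` dict with key
``"comparisons"`` is incremented so tests can certify linearity.  The
inputs must already be sorted — sorting happens once at dataset
construction, never here.
"""

from __future__ import annotations

import numpy as np

__all__ = ["step_lookup", "riskset_suffix_sums", "event_prefix_map"]


def _check_sorted(sorted_times: np.ndarray, event_times: np.ndarray) -> None:
    if sorted_times.size and np.any(np.diff(sorted_times) > 0):
        raise ValueError("subject times must be sorted in descending order")
    if event_times.size and np.any(np.diff(event_times) >= 0):
        raise ValueError("event times must be strictly decreasing")


def _bump(counter, amount: int = 1) -> None:
    if counter is not None:
        counter["comparisons"] = counter.get("comparisons", 0) + amount


def step_lookup(values_at_event_times: np.ndarray, event_times: np.ndarray,
                sorted_times: np.ndarray, counter: dict | None = None) -> np.ndarray:
    """Evaluate a descending-step function at every (descending) subject time.

    ``values_at_event_times[j]`` is the function value at ``event_times[j]``
    (strictly decreasing).  The output at subject time T is: the value at
    the largest event time if T is at or above it; the value at the next
    event time t_{k(j+1)} when T ∈ [t_{k(j+1)}, t_kj); and 0 below the
    smallest event time (closed on the right: T equal to an event time
    takes the value at that time).

    Works for vector-valued step functions: ``values_at_event_times`` may
    be (q_k,) or (q_k, d).
    """
    vals = np.asarray(values_at_event_times, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    sorted_times = np.asarray(sorted_times, dtype=float)
    _check_sorted(sorted_times, event_times)
    n = sorted_times.shape[0]
    q_k = event_times.shape[0]
    out_shape = (n,) if vals.ndim == 1 else (n, vals.shape[1])
    out = np.zeros(out_shape)
    if q_k == 0:
        return out
    if vals.shape[0] != q_k:
        raise ValueError("values and event times length mismatch")

    i = 0
    for j in range(q_k):
        # subjects with T >= t_kj that were not yet assigned take value at t_kj
        while i < n:
            _bump(counter)
            if sorted_times[i] >= event_times[j]:
                out[i] = vals[j]
                i += 1
            else:
                break
    # remaining subjects have T below the smallest event time: value 0
    return out


def riskset_suffix_sums(a: np.ndarray, event_times: np.ndarray,
                        sorted_times: np.ndarray, counter: dict | None = None) -> np.ndarray:
    """Σ_{r ∈ R(t_kj)} a_r for each descending event time t_kj.

    ``a`` is aligned to ``sorted_times`` (descending) and may be (n,) or
    (n, d).  R(t) = {r : T_r ≥ t} is closed at t.  Scanning event times
    from the largest down, each subject enters the running sum exactly
    once, so the cost is O(n + q_k).
    """
    a = np.asarray(a, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    sorted_times = np.asarray(sorted_times, dtype=float)
    _check_sorted(sorted_times, event_times)
    n = sorted_times.shape[0]
    if a.shape[0] != n:
        raise ValueError("per-subject values and subject times length mismatch")
    q_k = event_times.shape[0]
    d = None if a.ndim == 1 else a.shape[1]
    out = np.zeros((q_k,) if d is None else (q_k, d))
    running = 0.0 if d is None else np.zeros(d)
    i = 0
    for j in range(q_k):
        while i < n:
            _bump(counter)
            if sorted_times[i] >= event_times[j]:
                running = running + a[i]
                i += 1
            else:
                break
        out[j] = running
    return out


def event_prefix_map(b_kj: np.ndarray, event_times: np.ndarray,
                     sorted_times: np.ndarray, counter: dict | None = None) -> np.ndarray:
    """B(T_i) for all subjects, where B(t) = Σ_{j: t_kj ≤ t} b_kj.

    First accumulates B at the event times themselves by a suffix sum
    over the descending event-time array (each event time is ≤ all
    earlier-listed, i.e. larger, times), then maps to the subject times
    with the same merged scan as :func:`step_lookup`.  ``b_kj`` may be
    (q_k,) or (q_k, d).
    """
    b_kj = np.asarray(b_kj, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    q_k = event_times.shape[0]
    if q_k == 0:
        n = np.asarray(sorted_times).shape[0]
        return np.zeros((n,) if b_kj.ndim == 1 else (n, b_kj.shape[1]))
    if b_kj.shape[0] != q_k:
        raise ValueError("b_kj and event times length mismatch")
    # B at event times: B(t_kj) = b_kj + B(t_k(j+1)); suffix cumsum in descending array
    B_at_events = b_kj[::-1].cumsum(axis=0)[::-1]
    _bump(counter, q_k)
    return step_lookup(B_at_events, event_times, sorted_times, counter=counter)
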