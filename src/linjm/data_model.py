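"""Core domain types for joint longitudinal / competing-risks data.

A joint dataset pairs, for each subject, a series of longitudinal
measurements (linear mixed model design) with a single survival record
(observed time, cause of failure or censoring, baseline covariates).
All downstream algorithms assume a global ordering of subjects by
*descending* observed time, which is computed once here; the linear
scan primitives in :mod:`linjm.hazard_scan` rely on it and never sort.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SubjectLongitudinal",
    "SubjectSurvival",
    "JointDataset",
    "EventTimeIndex",
    "StepCumHazard",
    "ParameterSet",
    "build_dataset",
    "build_event_index",
]


@dataclass
class SubjectLongitudinal:
    """Longitudinal record for one subject.

    ``fixed_design`` holds one row per visit of the fixed-effect
    covariate vector X⁽¹⁾(t) (length p); ``random_design`` the
    random-effect covariate vector X̃⁽¹⁾(t) (length q).
    """

    subject_id: object
    times: np.ndarray          # (n_i,)
    responses: np.ndarray      # (n_i,)
    fixed_design: np.ndarray   # (n_i, p)
    random_design: np.ndarray  # (n_i, q)

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.responses = np.atleast_1d(np.asarray(self.responses, dtype=float))
        self.fixed_design = np.atleast_2d(np.asarray(self.fixed_design, dtype=float))
        self.random_design = np.atleast_2d(np.asarray(self.random_design, dtype=float))
        n_i = self.times.shape[0]
        if n_i < 1:
            raise ValueError(f"subject {self.subject_id!r}: needs at least one visit")
        if self.responses.shape != (n_i,):
            raise ValueError(f"subject {self.subject_id!r}: responses/times length mismatch")
        if self.fixed_design.shape[0] != n_i or self.random_design.shape[0] != n_i:
            raise ValueError(f"subject {self.subject_id!r}: design row count mismatch")
        if np.any(np.diff(self.times) < 0):
            raise ValueError(f"subject {self.subject_id!r}: visit times must be nondecreasing")
        for arr, name in ((self.times, "times"), (self.responses, "responses"),
                          (self.fixed_design, "fixed_design"), (self.random_design, "random_design")):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"subject {self.subject_id!r}: non-finite values in {name}")

    @property
    def n_obs(self) -> int:
        return self.times.shape[0]


@dataclass
class SubjectSurvival:
    """Survival record: observed time T, cause D in {0..K} (0 = censored),
    and time-invariant covariates X⁽²⁾."""

    subject_id: object
    time: float
    cause: int
    covariates: np.ndarray  # (p2,)

    def __post_init__(self) -> None:
        self.time = float(self.time)
        self.cause = int(self.cause)
        self.covariates = np.atleast_1d(np.asarray(self.covariates, dtype=float))
        if not np.isfinite(self.time) or self.time < 0:
            raise ValueError(f"subject {self.subject_id!r}: survival time must be finite and >= 0")
        if self.cause < 0:
            raise ValueError(f"subject {self.subject_id!r}: cause must be >= 0")
        if not np.all(np.isfinite(self.covariates)):
            raise ValueError(f"subject {self.subject_id!r}: non-finite survival covariates")


@dataclass
class JointDataset:
    """Aligned longitudinal + survival data with the descending-time order.

    ``desc_order`` is a permutation of ``range(n)`` such that
    ``surv_time[desc_order]`` is non-increasing (ties broken by subject
    position for determinism).
    """

    longitudinal: list    # of SubjectLongitudinal
    survival: list        # of SubjectSurvival
    n: int
    p: int
    q: int
    K: int
    p2: int
    desc_order: np.ndarray = field(default=None)  # type: ignore[assignment]

    # stacked observation-level arrays (built in __post_init__)
    y: np.ndarray = field(default=None, repr=False)        # (N,)
    X: np.ndarray = field(default=None, repr=False)        # (N, p)
    Z: np.ndarray = field(default=None, repr=False)        # (N, q)
    obs_subject: np.ndarray = field(default=None, repr=False)  # (N,) subject index per row
    row_starts: np.ndarray = field(default=None, repr=False)   # (n+1,) row range per subject
    surv_time: np.ndarray = field(default=None, repr=False)    # (n,)
    cause: np.ndarray = field(default=None, repr=False)        # (n,)
    X2: np.ndarray = field(default=None, repr=False)           # (n, p2)

    def __post_init__(self) -> None:
        if len(self.longitudinal) != self.n or len(self.survival) != self.n:
            raise ValueError("longitudinal and survival records must align one-to-one")
        for lon, sur in zip(self.longitudinal, self.survival):
            if lon.subject_id != sur.subject_id:
                raise ValueError(f"misaligned subject ids {lon.subject_id!r} vs {sur.subject_id!r}")
            if lon.fixed_design.shape[1] != self.p or lon.random_design.shape[1] != self.q:
                raise ValueError(f"subject {lon.subject_id!r}: design dimension mismatch")
            if sur.covariates.shape[0] != self.p2:
                raise ValueError(f"subject {sur.subject_id!r}: survival covariate length mismatch")
            if sur.cause > self.K:
                raise ValueError(f"subject {sur.subject_id!r}: cause {sur.cause} exceeds K={self.K}")
            if lon.times[-1] > sur.time:
                raise ValueError(
                    f"subject {lon.subject_id!r}: visit at {lon.times[-1]} after survival time {sur.time}")

        self.y = np.concatenate([s.responses for s in self.longitudinal])
        self.X = np.vstack([s.fixed_design for s in self.longitudinal])
        self.Z = np.vstack([s.random_design for s in self.longitudinal])
        n_obs = np.array([s.n_obs for s in self.longitudinal])
        self.row_starts = np.concatenate([[0], np.cumsum(n_obs)])
        self.obs_subject = np.repeat(np.arange(self.n), n_obs)
        self.surv_time = np.array([s.time for s in self.survival], dtype=float)
        self.cause = np.array([s.cause for s in self.survival], dtype=int)
        self.X2 = np.vstack([s.covariates for s in self.survival]) if self.n else np.zeros((0, self.p2))

        if self.desc_order is None:
            # stable sort on -time: ties broken by original position
            self.desc_order = np.argsort(-self.surv_time, kind="stable")
        self.desc_order = np.asarray(self.desc_order, dtype=int)
        t_sorted = self.surv_time[self.desc_order]
        if np.any(np.diff(t_sorted) > 0):
            raise ValueError("desc_order does not place survival times in descending order")
        self._inv_desc = np.empty(self.n, dtype=int)
        self._inv_desc[self.desc_order] = np.arange(self.n)

    @property
    def inv_desc_order(self) -> np.ndarray:
        """Inverse permutation of ``desc_order``."""
        return self._inv_desc

    @property
    def n_total_obs(self) -> int:
        return int(self.y.shape[0])

    @property
    def subject_ids(self) -> list:
        return [s.subject_id for s in self.longitudinal]

    def subject_rows(self, i: int) -> slice:
        return slice(int(self.row_starts[i]), int(self.row_starts[i + 1]))


@dataclass
class EventTimeIndex:
    """Distinct type-k event times in descending order with multiplicities.

    ``subject_event_j[i]`` gives, for a subject with cause k, the index j
    of its event time within ``times`` (−1 otherwise).
    """

    k: int
    times: np.ndarray           # (q_k,) strictly decreasing
    multiplicities: np.ndarray  # (q_k,) d_kj >= 1
    subject_event_j: np.ndarray  # (n,) index into times, −1 for non-type-k subjects

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.multiplicities = np.asarray(self.multiplicities, dtype=int)
        if self.times.size and np.any(np.diff(self.times) >= 0):
            raise ValueError("event times must be strictly decreasing")
        if np.any(self.multiplicities < 1):
            raise ValueError("event-time multiplicities must be >= 1")

    @property
    def q_k(self) -> int:
        return int(self.times.shape[0])


def build_event_index(dataset: JointDataset, k: int) -> EventTimeIndex:
    """Index the distinct type-``k`` event times of a dataset.

    Returns descending distinct times with multiplicities; an empty index
    (q_k = 0) when no type-k event occurred.
    """
    if not (1 <= k <= dataset.K):
        raise ValueError(f"k must be in 1..{dataset.K}")
    mask = dataset.cause == k
    ev_times = dataset.surv_time[mask]
    uniq, counts = np.unique(ev_times, return_counts=True)
    times = uniq[::-1].copy()
    mult = counts[::-1].copy()
    subject_event_j = np.full(dataset.n, -1, dtype=int)
    if times.size:
        # map each event subject to the position of its time in `times`
        asc = uniq  # ascending
        pos_asc = np.searchsorted(asc, dataset.surv_time[mask])
        subject_event_j[mask] = times.size - 1 - pos_asc
    return EventTimeIndex(k=k, times=times, multiplicities=mult,
                          subject_event_j=subject_event_j)


@dataclass
class StepCumHazard:
    """Right-continuous nondecreasing step cumulative baseline hazard.

    Jumps sit at the descending ``jump_times``; Λ(t) = sum of jumps at
    times ≤ t, hence 0 below the smallest jump time.
    """

    jump_times: np.ndarray  # (q_k,) strictly decreasing
    jumps: np.ndarray       # (q_k,) nonnegative

    def __post_init__(self) -> None:
        self.jump_times = np.asarray(self.jump_times, dtype=float)
        self.jumps = np.asarray(self.jumps, dtype=float)
        if self.jump_times.shape != self.jumps.shape:
            raise ValueError("jump_times and jumps must have the same shape")
        if self.jump_times.size and np.any(np.diff(self.jump_times) >= 0):
            raise ValueError("jump times must be strictly decreasing")
        if np.any(self.jumps < 0):
            raise ValueError("hazard jumps must be nonnegative")

    @property
    def cum_values(self) -> np.ndarray:
        """Λ evaluated at the jump times (descending order)."""
        return self.jumps[::-1].cumsum()[::-1]

    def at(self, t: float) -> float:
        """Λ(t) for a scalar t."""
        mask = self.jump_times <= t
        return float(self.jumps[mask].sum())


@dataclass
class ParameterSet:
    """Full parameter vector Ψ of the joint model.

    beta (p,), sigma2 > 0, Sigma (q, q) PSD, and per risk k: gamma[k]
    (p2,), nu[k] (q,), baselines[k] a :class:`StepCumHazard`.
    """

    beta: np.ndarray
    sigma2: float
    Sigma: np.ndarray
    gamma: list   # K arrays (p2,)
    nu: list      # K arrays (q,)
    baselines: list  # K StepCumHazard

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        self.sigma2 = float(self.sigma2)
        self.Sigma = np.asarray(self.Sigma, dtype=float)
        self.gamma = [np.asarray(g, dtype=float) for g in self.gamma]
        self.nu = [np.asarray(v, dtype=float) for v in self.nu]
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")
        if not np.allclose(self.Sigma, self.Sigma.T):
            raise ValueError("Sigma must be symmetric")
        w = np.linalg.eigvalsh(self.Sigma)
        if w.min() < -1e-10 * max(1.0, w.max()):
            raise ValueError("Sigma must be positive semi-definite")

    @property
    def K(self) -> int:
        return len(self.gamma)

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            beta=self.beta.copy(), sigma2=self.sigma2, Sigma=self.Sigma.copy(),
            gamma=[g.copy() for g in self.gamma], nu=[v.copy() for v in self.nu],
            baselines=[StepCumHazard(b.jump_times.copy(), b.jumps.copy()) for b in self.baselines],
        )


def build_dataset(longitudinal_table: pd.DataFrame, survival_table: pd.DataFrame,
                  *,
                  id_col: str = "id", time_col: str = "time", y_col: str = "y",
                  fixed_cols: list | None = None, random_cols: list | None = None,
                  fixed_intercept: bool = True, random_intercept: bool = True,
                  survtime_col: str = "survtime", cause_col: str = "cause",
                  surv_covariate_cols: list | None = None,
                  K: int | None = None) -> JointDataset:
    """Assemble a validated :class:`JointDataset` from two tables.

    The longitudinal table is long-format (one row per visit); the
    survival table has exactly one row per subject.  Fixed/random design
    matrices are built from the named columns, with an intercept column
    prepended when requested.  Subjects present in only one table raise.
    """
    fixed_cols = list(fixed_cols) if fixed_cols is not None else [time_col]
    random_cols = list(random_cols) if random_cols is not None else [time_col]
    surv_covariate_cols = list(surv_covariate_cols) if surv_covariate_cols is not None else [
        c for c in survival_table.columns if c not in (id_col, survtime_col, cause_col)]

    for col in [id_col, time_col, y_col, *fixed_cols, *random_cols]:
        if col not in longitudinal_table.columns:
            raise ValueError(f"longitudinal table is missing column {col!r}")
    for col in [id_col, survtime_col, cause_col, *surv_covariate_cols]:
        if col not in survival_table.columns:
            raise ValueError(f"survival table is missing column {col!r}")
    if longitudinal_table[[time_col, y_col, *fixed_cols, *random_cols]].isna().any().any():
        raise ValueError("longitudinal table contains missing values")
    if survival_table[[survtime_col, cause_col, *surv_covariate_cols]].isna().any().any():
        raise ValueError("survival table contains missing values")
    if survival_table[id_col].duplicated().any():
        dup = survival_table[id_col][survival_table[id_col].duplicated()].iloc[0]
        raise ValueError(f"survival table has duplicate rows for subject {dup!r}")

    long_ids = set(longitudinal_table[id_col])
    surv_ids = set(survival_table[id_col])
    if long_ids != surv_ids:
        missing = sorted(map(str, long_ids ^ surv_ids))[:5]
        raise ValueError(f"subject ids do not align across tables (e.g. {missing})")

    surv_indexed = survival_table.set_index(id_col)
    # preserve the survival-table subject order
    longitudinal, survival = [], []
    for sid in survival_table[id_col]:
        rows = longitudinal_table[longitudinal_table[id_col] == sid].sort_values(time_col, kind="stable")
        fixed = rows[fixed_cols].to_numpy(dtype=float)
        rand = rows[random_cols].to_numpy(dtype=float)
        if fixed_intercept:
            fixed = np.column_stack([np.ones(len(rows)), fixed])
        if random_intercept:
            rand = np.column_stack([np.ones(len(rows)), rand])
        longitudinal.append(SubjectLongitudinal(
            subject_id=sid, times=rows[time_col].to_numpy(dtype=float),
            responses=rows[y_col].to_numpy(dtype=float),
            fixed_design=fixed, random_design=rand))
        srow = surv_indexed.loc[sid]
        survival.append(SubjectSurvival(
            subject_id=sid, time=float(srow[survtime_col]), cause=int(srow[cause_col]),
            covariates=srow[surv_covariate_cols].to_numpy(dtype=float)))

    n = len(survival)
    if n == 0:
        raise ValueError("dataset has no subjects")
    p = longitudinal[0].fixed_design.shape[1]
    q = longitudinal[0].random_design.shape[1]
    p2 = survival[0].covariates.shape[0]
    observed_K = int(max((s.cause for s in survival), default=0))
    K_eff = K if K is not None else max(observed_K, 1)
    if observed_K > K_eff:
        raise ValueError(f"observed cause {observed_K} exceeds declared K={K_eff}")
    return JointDataset(longitudinal=longitudinal, survival=survival,
                        n=n, p=p, q=q, K=K_eff, p2=p2)
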