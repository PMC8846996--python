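import numpy as np
import pytest

from linjm.em_engine import EMSettings, fit
from linjm.simulate import SimTruth, simulate_joint


@pytest.fixture(scope="session")
def sim300():
    """Moderate simulated dataset shared by estimation tests."""
    return simulate_joint(SimTruth(n=300, seed=11))


@pytest.fixture(scope="session")
def fit300(sim300):
    """Converged pseudo-adaptive fit on the shared dataset."""
    return fit(sim300, EMSettings())


@pytest.fixture(scope="session")
def tight_fit30():
    """Tightly converged small fit used for fixed-point / score checks."""
    ds = simulate_joint(SimTruth(n=30, seed=3))
    res = fit(ds, EMSettings(tol_param=1e-7, tol_loglik=1e-13, max_iter=1500))
    return ds, res


def random_scan_instance(rng, n, qk_choice=None, integer=False, tie_prob=0.4):
    """A random (sorted_times, event_times, a) triple with ties."""
    if integer:
        times = rng.integers(0, max(2, n // 2), size=n).astype(float)
    else:
        times = rng.random(n) * 10
        dup = rng.random(n) < tie_prob
        times[dup] = np.round(times[dup], 0)
    times = np.sort(times)[::-1].copy()
    if qk_choice is None:
        qk_choice = rng.choice([0, 1, max(1, n // 2)])
    uniq = np.unique(times)[::-1]
    q_k = int(min(qk_choice, uniq.size))
    ev = np.sort(rng.choice(uniq, size=q_k, replace=False))[::-1].copy() if q_k else np.zeros(0)
    if integer:
        a = rng.integers(-5, 6, size=n).astype(float)
    else:
        a = rng.normal(size=n)
    return times, ev, a
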