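import numpy as np
import pytest

from coxmdr.cohort import Cohort


def make_cohort(time, status, covariates=None, genotypes=None, ids=None):
    n = len(time)
    if covariates is None:
        covariates = np.empty((n, 0))
    if genotypes is None:
        genotypes = np.zeros((n, 1), dtype=np.int8)
    if ids is None:
        ids = np.array([f"s{i}" for i in range(n)])
    return Cohort(ids=ids, time=np.asarray(time, float),
                  status=np.asarray(status), covariates=np.asarray(covariates),
                  genotypes=np.asarray(genotypes))


def random_cohort(rng, n=30, q=1, M=3, event_frac=0.7):
    """Random survival cohort with exponential times and HWE-ish genotypes."""
    time = rng.exponential(1.0, n) + 1e-3
    status = (rng.random(n) < event_frac).astype(int)
    if status.sum() == 0:
        status[rng.integers(n)] = 1
    Z = rng.normal(size=(n, q)) if q else np.empty((n, 0))
    G = rng.choice(3, size=(n, M), p=[0.49, 0.42, 0.09])
    return make_cohort(time, status, Z, G)


@pytest.fixture
def toy3():
    """Three subjects, all events, no covariates: closed-form Nelson-Aalen."""
    return make_cohort([1.0, 2.0, 3.0], [1, 1, 1])


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
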