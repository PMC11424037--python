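import numpy as np
import pytest

import necdyn as nd


def random_stable_system(n: int, rng: np.random.Generator, sigma2: float = 1.0):
    """Random stable (model, steady_state) pair via the covariance construction."""
    model = nd.random_stable_ec(n, asymmetry=float(rng.uniform(0.2, 1.0)),
                                seed=rng, sigma2=sigma2)
    return model, nd.steady_state(model)


@pytest.fixture(scope="session")
def hrf_prior():
    """Shared Balloon-Windkessel FIR prior (L = 18, TR = 1 s)."""
    return nd.sample_hrf_prior(n_samples=2000, TR=1.0, L=18, seed=3)


@pytest.fixture(scope="session")
def bench_recording(hrf_prior):
    """5-node asymmetric benchmark recording (T = 4000, TR = 1 s)."""
    rec, truth = nd.synthesize_recording(
        n=5, n_time=4000, TR=1.0, seed=11, hrf_prior=hrf_prior
    )
    return rec, truth


@pytest.fixture(scope="session")
def bench_fit(hrf_prior, bench_recording):
    """Unconstrained sparse-DCM fit of the benchmark recording."""
    rec, _ = bench_recording
    return nd.fit_sparse_dcm(rec, hrf_prior, {"max_iter": 60, "n_ard": 20})


@pytest.fixture()
def rotation_model():
    """2-node rotation family member with s = 1: A = -I + [[0,1],[-1,0]]."""
    return nd.LinearModel(A=np.array([[-1.0, 1.0], [-1.0, -1.0]]), sigma2=2.0)
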