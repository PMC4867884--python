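import numpy as np
import pytest

import ksegment as ks


def random_gaussian_model(rng, M, spread=2.0):
    """Random valid Gaussian HMM with strictly positive transition rows."""
    return ks.HMMParams(
        M=M,
        pi0=rng.dirichlet(np.ones(M) * 5),
        A=np.vstack([rng.dirichlet(np.ones(M) * 2) for _ in range(M)]),
        emission_family="gaussian",
        emission_params={
            "means": rng.normal(scale=spread, size=M),
            "variances": rng.uniform(0.3, 1.5, size=M),
        },
    )


def random_instance(seed, M=None, N=None):
    """(model, observations) pair small enough for exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    M = M or int(rng.integers(2, 4))
    N = N or int(rng.integers(4, 9))
    model = random_gaussian_model(rng, M)
    y = rng.normal(scale=2.0, size=N)
    return model, y


@pytest.fixture(scope="session")
def benchmark():
    """One seeded replicate of the three-state Gaussian benchmark design,
    with the EM fit used by the retrospective analyses."""
    design = ks.SimulationDesign()
    x, y = ks.simulate_hmm(design, seed=1)
    fitted, trace = ks.em_fit(ks.informative_init(y), y)
    return {
        "design": design,
        "model_true": design.model(),
        "x": x,
        "y": y,
        "fitted": fitted,
        "trace": trace,
    }


@pytest.fixture(scope="session")
def tiny_enumerable():
    """M=2, N=4 instance with its exhaustive path table (16 paths)."""
    model, y = random_instance(seed=123, M=2, N=4)
    return model, y, ks.enumerate_posterior(model, y)
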