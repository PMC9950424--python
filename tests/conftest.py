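import numpy as np
import pytest

from adprog.dynamics import VelocityParams, sparsity_mask
from adprog.model import ModelConfig, ProgressionModel
from adprog.synthetic import GeneratorConfig, generate_cohort, make_fixture


def random_stable_system(rng: np.random.Generator):
    """Random affine system with spectrum shifted left so 20-year horizons stay bounded."""
    A = 0.15 * rng.standard_normal((5, 5)) - 0.25 * np.eye(5)
    b = 0.3 * rng.standard_normal(5)
    return A, b


def random_velocity_params(rng: np.random.Generator, scale: float = 0.1) -> VelocityParams:
    mask = sparsity_mask()
    mats = []
    for _ in range(3):
        M = scale * rng.standard_normal((5, 5))
        M[mask] = 0.0
        mats.append(M)
    return VelocityParams(V=mats[0], W_age=mats[1], W_apoe=mats[2], v0=scale * rng.standard_normal(5))


@pytest.fixture(scope="session")
def tiny_cohort():
    return make_fixture("tiny")


@pytest.fixture(scope="session")
def fitted_small():
    """A fitted model on a dense synthetic cohort, shared across tests."""
    gen = GeneratorConfig(n_subjects=80, n_sites=4, seed=42, regular_visits=4, regular_followup=3.0)
    cohort, truth = generate_cohort(gen)
    config = ModelConfig(chains=2, warmup=600, draws=500, seed=3)
    results = ProgressionModel(cohort, config).fit()
    return cohort, truth, results
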