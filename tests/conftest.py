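import numpy as np
import pytest

from cyclefit import ModelParams, Profile, evaluate_model


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_profile(
    params: ModelParams,
    m: int,
    delta: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
    gene_id: str = "g",
) -> Profile:
    """Profile from the noise-free model, optionally with Gaussian noise."""
    values = evaluate_model(params, m, delta)
    if noise_sd > 0:
        values = values + noise_sd * np.random.default_rng(seed).standard_normal(m)
    return Profile(gene_id=gene_id, values=values, delta=delta)


@pytest.fixture
def smooth_params():
    """A well-conditioned parameter set: slow damping, mid-range frequency."""
    return ModelParams(alpha=-0.1, omega=1.0, a=1.0, b=0.5, c=0.05, d=2.0)
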