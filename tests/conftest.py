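import numpy as np
import pytest

from srnasilence.model_core import KineticParameters, get_preset


@pytest.fixture
def fig2_params() -> KineticParameters:
    return get_preset("fig2")


@pytest.fixture
def fig5_params() -> KineticParameters:
    return get_preset("fig5")


def random_valid_params(rng: np.random.Generator) -> KineticParameters:
    """Random parameter set inside the documented domain (shared oracle sweep)."""

    def lu(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return KineticParameters(
        alpha_m=lu(0.1, 10.0),
        alpha_s=0.0 if rng.random() < 0.15 else lu(0.01, 10.0),
        beta_m0=lu(0.05, 2.0),
        beta_s=lu(0.01, 1.0),
        beta_p=lu(0.005, 0.5),
        k0=lu(0.001, 1.0),
        gamma0=lu(0.1, 10.0),
        x=0.0 if rng.random() < 0.1 else lu(1e-3, 100.0),
        w=lu(0.1, 10.0),
        y=lu(0.01, 100.0),
        z=0.0 if rng.random() < 0.1 else lu(1e-4, 1.0),
    )
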