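import numpy as np
import pytest

from segpower import SimulationConfig, build_spatial_model

# baseline scenario used across simulator-facing tests:
# 6x6 lattice, sigma_rho=0.7, omega=128, psi=15%, delta=3%
BASELINE = dict(delta=0.03, psi=0.15, omega=128.0)


@pytest.fixture(scope="session")
def baseline_spatial():
    return build_spatial_model((6, 6), 0.7)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def baseline_config(spatial, n_images, n_reps=1, seed=0, **overrides):
    params = {**BASELINE, **overrides}
    return SimulationConfig.from_delta_psi(
        spatial,
        params["delta"],
        params["psi"],
        params["omega"],
        n_images=n_images,
        n_reps=n_reps,
        seed=seed,
    )
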