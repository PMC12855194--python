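import numpy as np
import pytest

from phenoswitch import MixtureSpec, SwitchingParams

#: observation schedule of the growth-cycle assays (hours)
OBS_TIMES = [12.0, 20.0, 24.0, 48.0]

#: default analysis grid (see phenoswitch.pipeline._DEFAULT_GRIDS)
GRIDS = {
    "alpha_grid": [0.05, 0.2, 1.0],
    "beta_grid": [0.001, 0.005, 0.02],
    "gamma_grid": [0.0, 0.05],
    "k_grid": [0.001, 0.1, 1.0],
}


@pytest.fixture
def best_fit_params() -> SwitchingParams:
    """The deterministic best-fit parameter tuple of the switching model."""
    return SwitchingParams(alpha=1.0, beta=0.005, gamma=0.0, k=0.001)


@pytest.fixture
def separated_spec() -> MixtureSpec:
    """Well-separated diameter mixture (4-sigma separation, means 5/25 um)."""
    return MixtureSpec(
        weight_small=0.5, mean_small=5.0, sd_small=1.0,
        mean_large=25.0, sd_large=5.0, detection_threshold=3.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
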