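import numpy as np
import pytest

from awsom import phantom as ph
from awsom.glm import GLMModel, build_design_matrix


@pytest.fixture(scope="session")
def grid48() -> ph.GridSpec:
    """Smallest grid on which the default ROA layout fits comfortably."""
    return ph.GridSpec(shape=(48, 48, 48))


@pytest.fixture(scope="session")
def hrf_fine() -> np.ndarray:
    return ph.make_hrf(ph.HRFSpec(), dt_s=0.01)


@pytest.fixture(scope="session")
def noiseless_phantom(grid48) -> ph.Phantom4D:
    return ph.make_phantom(grid=grid48, bold_pct=6.0)


@pytest.fixture(scope="session")
def noisy_phantom(grid48) -> ph.Phantom4D:
    return ph.make_phantom(
        grid=grid48, bold_pct=6.0,
        noise=ph.NoiseSpec(kind="gaussian", level_pct=2.0, seed=11),
    )


@pytest.fixture(scope="session")
def noisy_glm(noisy_phantom):
    return GLMModel(
        noisy_phantom.data, build_design_matrix(noisy_phantom.regressor),
        noisy_phantom.brain_mask,
    ).fit()
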