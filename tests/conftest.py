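import numpy as np
import pytest
import SimpleITK as sitk

from olfrecon.phantom import PhantomConfig, make_series
from olfrecon.registration import RegistrationConfig

# single-threaded ITK: the registration determinism contract assumes it
sitk.ProcessObject.SetGlobalDefaultNumberOfThreads(1)


@pytest.fixture(scope="session")
def small_config() -> PhantomConfig:
    """A fully included, undeformed 6-section specimen."""
    return PhantomConfig(
        grid_shape=(6, 128, 128), dropout_rate=0.0, deform_amplitude=0.0,
        banana_curvature=0.0, seed=3,
    )


@pytest.fixture(scope="session")
def small_series(small_config):
    return make_series(small_config)


@pytest.fixture(scope="session")
def jittered_series():
    """A 10-section stack with per-section smooth jitter only."""
    cfg = PhantomConfig(
        grid_shape=(10, 128, 128), dropout_rate=0.0, deform_amplitude=2.0,
        banana_curvature=0.0, seed=5,
    )
    return make_series(cfg)


@pytest.fixture(scope="session")
def fast_reg() -> RegistrationConfig:
    """Registration settings sized for 128-px test images."""
    return RegistrationConfig(max_iterations=50, bspline_mesh=5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
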