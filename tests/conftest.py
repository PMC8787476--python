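import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def standin_model():
    """Two-trimer synthetic PERV-TM-like model (6 chains, 2 chlorides)."""
    from sixhelix.perv_standin import build_standin

    return build_standin(n_trimers=2)


@pytest.fixture(scope="session")
def standin_trimer():
    from sixhelix.perv_standin import build_standin

    return build_standin(n_trimers=1)


@pytest.fixture(scope="session")
def standin_axis(standin_trimer):
    from sixhelix.coiled_coil import fit_bundle_axis
    from sixhelix.pipeline import core_segments

    return fit_bundle_axis(core_segments(standin_trimer))


@pytest.fixture
def rng():
    return np.random.default_rng(20261001)
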