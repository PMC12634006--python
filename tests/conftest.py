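import numpy as np
import pytest

from etgcsf import CSFParams, EngineConfig, QcsfEngine, protocol_preset


@pytest.fixture(scope="session")
def worked_params():
    """The worked truncated log-parabola example used across modules."""
    return CSFParams(gamma_max=100.0, f_max=2.0, beta=3.0, delta=0.5)


@pytest.fixture(scope="session")
def small_engine_config():
    """A coarse grid/space pair for fast exhaustive-search comparisons."""
    return EngineConfig(
        n_gamma=5, n_f_max=4, n_beta=3, n_delta=2, n_sf=4, n_contrast=5,
        sf_range=(0.5, 32.0),
    )


@pytest.fixture(scope="session")
def exp1_engine():
    """Full-resolution engine for the baseline (60-trial) protocol, shared."""
    return QcsfEngine(protocol_preset("exp1").engine_config())


@pytest.fixture(scope="session")
def exp2_engine():
    return QcsfEngine(protocol_preset("exp2").engine_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
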