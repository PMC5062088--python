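import numpy as np
import pytest

from echoqdi import AcquisitionConfig, compute_envelope
from echoqdi.phantom_simulator import PhantomSpec, simulate_rf_frame


@pytest.fixture(scope="session")
def config():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def speckle_frame(config):
    """Fully developed speckle: 15 scatterers per resolution cell, no attenuation."""
    return simulate_rf_frame(PhantomSpec(scatterer_density=15.0, beta=0.0, seed=42), config)


@pytest.fixture(scope="session")
def speckle_envelope(speckle_frame):
    return compute_envelope(speckle_frame)


@pytest.fixture(scope="session")
def small_frame():
    """Short, narrow frame for cheap pointwise-oracle tests."""
    cfg = AcquisitionConfig(n_lines=32)
    return simulate_rf_frame(
        PhantomSpec(scatterer_density=12.0, depth_extent=2.0, seed=3), cfg
    )
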