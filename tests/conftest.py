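import numpy as np
import pytest

from drfkit import DistractionProtocol, OgdenParams, SegmentGeometry, SensorArrayGeometry


@pytest.fixture
def soft_tissue() -> OgdenParams:
    """The ovine soft-tissue envelope parameters (mu = 700 kPa, alpha = 20)."""
    return OgdenParams(mu=700e3, alpha=20.0, d1=0.0)


@pytest.fixture
def ring() -> SensorArrayGeometry:
    return SensorArrayGeometry()


@pytest.fixture
def cylinder() -> SegmentGeometry:
    return SegmentGeometry()


@pytest.fixture
def protocol() -> DistractionProtocol:
    return DistractionProtocol()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
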