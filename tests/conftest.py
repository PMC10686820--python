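import numpy as np
import pytest

from gva import ConeGeometry


@pytest.fixture
def p200() -> ConeGeometry:
    """The standard 200 µL pipette-tip geometry: 36 mm axis, 150 µL gel."""
    return ConeGeometry("circular_cone", 36.0, 150.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
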