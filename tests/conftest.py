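import numpy as np
import pytest

from lysoquant.io import CellGeometry
from lysoquant.simulate import circle_polygon


@pytest.fixture
def concentric_cell() -> CellGeometry:
    """Concentric circles: nucleus radius 5, cell radius 15, centred at origin."""
    return CellGeometry(
        circle_polygon((0.0, 0.0), 15.0, n=720),
        circle_polygon((0.0, 0.0), 5.0, n=720),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
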