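import numpy as np
import pytest
from shapely.geometry import box

from ccisim import SpatialWindow, generate_reference


@pytest.fixture(scope="session")
def unit_window():
    return SpatialWindow(box(0.0, 0.0, 1.0, 1.0))


@pytest.fixture(scope="session")
def paired_bundle():
    """Small paired reference with no planted effects."""
    bundle, truth = generate_reference("paired", n_cells=300, n_genes=40, n_types=3, seed=42)
    return bundle, truth


@pytest.fixture(scope="session")
def uniform_points():
    return np.random.default_rng(7).random((200, 2))
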