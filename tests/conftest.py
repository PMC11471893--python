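"""Shared fixtures: small synthetic volumes reused across layer-line tests.

All fixtures are generated programmatically; the desk-scale geometry is a
256-px analysis box at 4.34 Å/px (1,111 Å physical edge) except where a test
needs the full 2,235.1 Å reciprocal grid.
"""

import matplotlib
import numpy as np
import pytest

matplotlib.use("Agg")

from mtlattice import (MeasureConfig, centered_filament_spec,
                       simulate_filament_volume)

VOXEL = 4.34
SMALL_DIMS = (96, 300, 72)
SMALL_BOX = 256


@pytest.fixture(scope="session")
def small_cfg():
    return MeasureConfig(box=SMALL_BOX, search_min_A=38.0, search_max_A=46.0)


@pytest.fixture(scope="session")
def small_filament():
    """Noise-free 41 Å lattice along +y in a small grid, with backbone."""
    spec = centered_filament_spec(41.0, SMALL_DIMS, VOXEL)
    vol, bb = simulate_filament_volume(spec, SMALL_DIMS, VOXEL)
    return spec, vol, bb


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240)
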