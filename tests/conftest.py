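import numpy as np
import pytest

from dmiquant.grids import GridGeometry
from dmiquant.pipeline import run_reference_calibration
from dmiquant.synthetic import ProtocolParams, make_phantom_truth


@pytest.fixture(scope="session")
def small_grid():
    return GridGeometry((8, 8, 4), (220.0, 200.0, 320.0))


@pytest.fixture(scope="session")
def ref_truth_small(small_grid):
    """Noise-free reference-phantom ground truth on a small grid."""
    return make_phantom_truth("uniform_reference", small_grid, 4, seed=1)


@pytest.fixture(scope="session")
def protocols_small():
    return (ProtocolParams.voltage_series(256), ProtocolParams.main_scan(256))


@pytest.fixture(scope="session")
def noiseless_calibration(ref_truth_small, protocols_small):
    """Full calibration chain run once on noiseless simulated data."""
    cal, main = protocols_small
    bundle, ref_spec = run_reference_calibration(
        ref_truth_small, cal, main, add_noise=False, seed=1)
    return bundle, ref_spec


@pytest.fixture
def rng():
    return np.random.default_rng(0)
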