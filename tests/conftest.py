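import numpy as np
import pytest

from epimap.features import ActivationMap
from epimap.synthetic import make_geometry, simulate_planar_truth, synthesize_recording


@pytest.fixture(scope="session")
def grid16x8():
    return make_geometry(16, 8, 2.7)


@pytest.fixture(scope="session")
def grid4x4():
    return make_geometry(4, 4, 1.0)


@pytest.fixture(scope="session")
def planar_truth(grid16x8):
    """Planar wave at 0.9 m/s along +x; activation times are exact sample
    multiples (3 ms column steps at 25 kHz) starting 20 ms post-stimulus."""
    return simulate_planar_truth(grid16x8, 0.9, 0.0, 20.0)


@pytest.fixture(scope="session")
def noiseless_recording(planar_truth):
    """Single-beat noiseless recording, 0.6 s, stimulus at t = 0."""
    return synthesize_recording(planar_truth, ari_ms=180.0, noise_sd_mv=0.0,
                                seed=0, duration_s=0.6, stimulus_times_ms=(0.0,))


@pytest.fixture()
def truth_map(planar_truth):
    return ActivationMap.from_times(planar_truth.times_ms)


def brute_force_extreme_slope(signal_row, fs_hz, i0, i1, mode):
    """Independent oracle: exhaustive scan of the central-difference
    derivative over inclusive sample range [i0, i1]; earliest tie wins.

    Returns (index, slope_mv_per_ms).
    """
    dt_ms = 1000.0 / fs_hz
    best_i, best_v = None, None
    for i in range(i0, i1 + 1):
        v = (float(signal_row[i + 1]) - float(signal_row[i - 1])) / (2.0 * dt_ms)
        if best_v is None or (v < best_v if mode == "min" else v > best_v):
            best_i, best_v = i, v
    return best_i, best_v


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
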