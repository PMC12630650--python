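import numpy as np
import pytest

from biofilmq.calibration import PUBLISHED_CURVE, CalibrationTable, ratio_from_ph


@pytest.fixture
def curve():
    return PUBLISHED_CURVE


@pytest.fixture
def noiseless_table(curve):
    """21 noiseless (pH, ratio) pairs over the buffer titration grid."""
    ph = np.round(np.arange(4.0, 8.0 + 1e-9, 0.2), 10)
    r = ratio_from_ph(ph, curve)
    return CalibrationTable(ph=ph, mean_ratio=r, sd_ratio=np.zeros_like(r),
                            n_fov=np.ones_like(r, dtype=int))


def brute_force_count_above(image, threshold):
    """Independent pixel recount: plain Python loop, no vectorised path."""
    count = 0
    for row in np.asarray(image):
        for v in row:
            if v > threshold:
                count += 1
    return count
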