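import numpy as np
import pytest

import spikeloc as sl


@pytest.fixture(scope="session")
def probe96():
    """Desk-scale staggered probe."""
    return sl.make_probe(96)


@pytest.fixture(scope="session")
def column_probe():
    """Single column of 16 channels, 20 µm pitch."""
    return sl.make_probe(16, {"layout": "single_column", "pitch_um": 20.0})


@pytest.fixture(scope="session")
def clean_sim(probe96):
    """Small clean simulation shared by read-only tests: 10 units, 5 s."""
    units = sl.sample_ground_truth(probe96, 10, duration_s=5.0, seed=0)
    rec = sl.render_recording(units, probe96, duration_s=5.0, seed=0)
    return probe96, units, rec


def monopole_ptp(geometry, source, c):
    """Forward-model oracle: ptp_j = c / ||source - p_j||."""
    d = np.linalg.norm(geometry.positions - np.asarray(source, dtype=float), axis=1)
    return c / d
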