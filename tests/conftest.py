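import numpy as np
import pytest
from hypothesis import settings

import impcbf as ic

settings.register_profile("default", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def base_truth():
    return ic.KineticGroundTruth()


@pytest.fixture(scope="session")
def noise_free_session(base_truth):
    """One noise-free acquisition at f_true = 50, full 30-min horizon."""
    return ic.simulate_session(base_truth, seed=0, noise=False)


@pytest.fixture(scope="session")
def calibration():
    """REICA slope-to-flow factor from the noise-free f = 20..80 grid."""
    return ic.reica_calibration_factor()


@pytest.fixture(scope="session")
def flow_sweep(base_truth, calibration):
    """Noise-free quantification of all three methods over f_true = 20..80."""
    flows = np.arange(20.0, 81.0, 10.0)
    out = {}
    for f in flows:
        sess = ic.simulate_session(base_truth.with_flow(f), noise=False)
        out[f] = ic.quantify_session(sess, reica_calibration=calibration)
    return out
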