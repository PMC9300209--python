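import numpy as np
import pytest

#: auxiliary parameter values of a well-calibrated restriction-digest assay
AUX = {"delta_T": 1.2, "delta_B": 0.24, "z": 0.0016, "eta": 0.97, "sigma_c": 0.2}

#: reference calibration truth used across calibration tests
CAL_TRUTH = {
    "mean_dna": 1.256e-6,
    "delta_T": 1.170,
    "delta_B": 0.2361,
    "sigma_c": 0.2376,
    "z": 0.001564,
    "eta": 0.9712,
}


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


@pytest.fixture
def aux():
    return dict(AUX)


@pytest.fixture
def cal_truth():
    return dict(CAL_TRUTH)
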