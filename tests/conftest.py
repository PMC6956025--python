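import warnings

import numpy as np
import pytest

import eogclean as ec
from eogclean.ica import ConvergenceWarning

warnings.simplefilter("ignore", ConvergenceWarning)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def small_recording(rng):
    data = rng.normal(0.0, 20.0, size=(4, 1000))
    return ec.Recording(data=data, fs=200.0, labels=["Fp1", "Fp2", "O1", "O2"])


@pytest.fixture(scope="session")
def blink_dataset():
    """Semi-simulated dataset with blinks only (no saccades), fixed seed."""
    return ec.make_dataset(saccade_rate_per_min=0.0, seed=3)


@pytest.fixture(scope="session")
def montage():
    return ec.Montage(frontal=ec.FRONTAL_1020)


@pytest.fixture(scope="session")
def pm_result(blink_dataset, montage):
    """Selective-method cleaning of the blink dataset (shared across tests)."""
    return ec.remove_eog(blink_dataset.contaminated, montage, method="pm", seed=3)
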