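import numpy as np
import pytest

from megms import synth
from megms.containers import MicrostateSet


@pytest.fixture(scope="session")
def layout32():
    return synth.make_layout(32, seed=11)


@pytest.fixture(scope="session")
def meg_maps(layout32):
    return synth.make_topographies(4, layout32, "meg", seed=12)


@pytest.fixture(scope="session")
def eeg_maps(layout32):
    return synth.make_topographies(4, layout32, "eeg", seed=13)


@pytest.fixture(scope="session")
def meg_rest(layout32, meg_maps):
    """A short, clean resting recording plus its ground truth (MEG mode)."""
    return synth.simulate_resting(
        layout32, meg_maps, duration_s=30.0, fs=250.0, snr=10.0, seed=14
    )


@pytest.fixture(scope="session")
def meg_templates(meg_maps):
    return MicrostateSet(meg_maps, "meg")


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
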