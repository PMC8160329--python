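import numpy as np
import pytest

from oxyflow import synth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_network():
    """A seeded random capillary network used by several morphometry tests."""
    truth = synth.NetworkTruth(volume_shape=(100, 100, 100), voxel_size=2.0,
                               target_density=0.9, seed=11)
    vol, stats = synth.make_volume(truth)
    return vol, stats


@pytest.fixture(scope="session")
def hemo_session():
    """A probe session with five metabolic events of known gains."""
    truth = synth.HemoTruth(duration=120.0,
                            cmro2_event_times=(20.0, 40.0, 60.0, 80.0, 100.0),
                            cmro2_gain=0.3, hbt_gain=0.06, noise_sd=0.0, seed=5)
    return synth.make_hemo(truth), truth
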