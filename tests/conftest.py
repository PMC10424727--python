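import numpy as np
import pytest

from ecgtracks import synth


@pytest.fixture(scope="session")
def sinus_record():
    spec = synth.RhythmSpec.for_class("sinus", seed=11)
    return synth.simulate_record(spec, duration_s=20.0, fs=300.0)


@pytest.fixture(scope="session")
def af_record():
    spec = synth.RhythmSpec.for_class("af", seed=12)
    return synth.simulate_record(spec, duration_s=60.0, fs=300.0)


@pytest.fixture(scope="session")
def small_mixed_suite():
    """10 records across the four rhythm classes, with ground truth."""
    mix = {"sinus": 3, "af": 3, "tachy": 2, "brady": 2}
    return synth.simulate_dataset(mix, dialect="cinc2017", seed=21,
                                  duration_s=20.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
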