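import numpy as np
import pytest

from tinda import StateTimeCourse


@pytest.fixture
def rng():
    return np.random.default_rng(20250901)


@pytest.fixture
def random_stc(rng):
    """A random 4-state sequence long enough for interval statistics."""
    labels = rng.integers(1, 5, size=5000)
    return StateTimeCourse(labels=labels, fs=250.0, K=4, subject_id="rand")


def make_stc(labels, fs=250.0, K=None, **kwargs):
    labels = np.asarray(labels)
    return StateTimeCourse(labels=labels, fs=fs,
                           K=K or int(labels.max()), **kwargs)
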