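import numpy as np
import pytest

from belugabuzz.buzzfeatures import ClickTrain
from belugabuzz.synthdata import gen_buzz_dataset


def train_from_ici(ici_ms, train_id="t", context="unknown", t0=0.0):
    """Build a click train whose ICI sequence (ms) is exactly as given."""
    times = t0 + np.concatenate([[0.0], np.cumsum(np.asarray(ici_ms, float)) / 1000.0])
    return ClickTrain(train_id=train_id, context=context, click_times=times)


@pytest.fixture(scope="session")
def buzz_dataset():
    """Seeded 18-feeding/19-social labeled dataset plus its feature table."""
    rng = np.random.default_rng(2018)
    return gen_buzz_dataset(rng=rng)
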