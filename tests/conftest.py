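import numpy as np
import pytest

from ecgkit import BEAT_CLASSES, make_dataset, normalize


@pytest.fixture(scope="session")
def small_bundle():
    """100 beats, 20 per class, default settings."""
    return make_dataset([20] * len(BEAT_CLASSES), seed=42)


@pytest.fixture(scope="session")
def clean_beat():
    """One normalized clean beat (class N) for denoising tests."""
    b = make_dataset({c: 1 for c in BEAT_CLASSES}, seed=7)
    i = int(np.flatnonzero(b.labels == "N")[0])
    return normalize(b.segments[i])
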