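import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def clean_screen():
    from yolobt import synthetic_eeg as se
    return se.generate_background(se.GenConfig(n_channels=8, seed=3))
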