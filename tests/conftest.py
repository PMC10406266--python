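import logging

import numpy as np
import pytest

from mreeg.core_io import SessionConfig
from mreeg.synthetic import assemble_session

logging.getLogger("mreeg").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_session():
    """A short resting session at desk scale: 8 scalp + 6 CWL + ECG, 250 Hz."""
    cfg = SessionConfig(fs_hz=250.0, duration_s=44.0, task="resting", seed=7,
                        n_scalp=8, neural={"block_s": 10.0, "n_blocks": 4})
    return assemble_session(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
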