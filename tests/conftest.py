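import numpy as np
import pytest

from npcrowd.config import load_preset
from npcrowd.phantoms import make_interphase_image, make_timelapse


@pytest.fixture(scope="session")
def peripheral_noise_free():
    """Noise-free 'peripheral' phantom: (donor, acceptor, manifest)."""
    cfg = load_preset("peripheral", noise="none", seed=3)
    return make_interphase_image(cfg)


@pytest.fixture(scope="session")
def early_assembler_stack():
    """Noise-free 'early_assembler' time-lapse: (stack, manifest, config)."""
    cfg = load_preset("early_assembler", noise="none", seed=2)
    stack, manifest = make_timelapse(cfg)
    return stack, manifest, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
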