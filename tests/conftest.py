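import numpy as np
import pytest

from orgamorph.synthetic import SimConfig, generate_scene


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 256x256 scene with organoids and distractors."""
    cfg = SimConfig(
        height=256, width=256, n_organoids=5, n_outfocus_distractors=2, seed=42
    )
    image, mask, objects = generate_scene(cfg)
    return cfg, image, mask, objects


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
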