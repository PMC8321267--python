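import numpy as np
import pytest

from derm2macro import synthetic


@pytest.fixture(scope="session")
def small_two_domain():
    """Six images per domain at 32 px with every artifact forced on/off
    deterministically enough for detector checks."""
    cfg = synthetic.SyntheticDatasetConfig(
        n_images=6, image_size=32, seed=11,
        artifact_probabilities={"dermo": {"dark_corners": 1.0},
                                "macro": {"glare": 1.0}})
    return synthetic.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def disc_spec():
    return synthetic.LesionSpec(center=(0.5, 0.5), radius=0.25,
                                boundary_harmonics=())
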