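import numpy as np
import pytest

from memwire.synthetic import SyntheticSpec, generate_system


@pytest.fixture(scope="session")
def base_system():
    """One default toy system shared by read-only tests."""
    return generate_system(SyntheticSpec(seed=11, n_frames=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_bundle(seed: int = 0, n_frames: int = 1, **overrides):
    """Fresh generator bundle for tests that mutate coordinates."""
    return generate_system(SyntheticSpec(seed=seed, n_frames=n_frames, **overrides))
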