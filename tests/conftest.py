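import numpy as np
import pytest

from crossatlas.qc import normalize_up10k
from crossatlas.simulate import AtlasSimSpec, simulate_atlas


@pytest.fixture(scope="session")
def atlas():
    """One simulated discrete-type sample shared across read-only tests."""
    spec = AtlasSimSpec()
    cm, meta, truth = simulate_atlas(spec, seed=1)
    return spec, cm, meta, truth


@pytest.fixture(scope="session")
def atlas_norm(atlas):
    _, cm, meta, truth = atlas
    return normalize_up10k(cm), meta, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
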