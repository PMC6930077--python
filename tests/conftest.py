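import numpy as np
import pytest

from repsim.germline import default_reference
from repsim.model import GeneratorConfig
from repsim.simulate import generate_repertoire, tissue_preset


@pytest.fixture(scope="session")
def reference():
    return default_reference()


@pytest.fixture(scope="session")
def small_repertoire(reference):
    """Small spleen repertoire with ground truth, shared across tests."""
    cfg = GeneratorConfig(preset=tissue_preset("spleen"),
                          n_clonotypes=400, seed=7)
    return generate_repertoire(cfg, reference)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
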