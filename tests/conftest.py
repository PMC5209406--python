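import numpy as np
import pytest

from chiqspr.dataset import load_structures, load_test, load_training
from chiqspr.molgraph import parse_smiles
from chiqspr.synthetic_data import SynthesisConfig, random_molecule

GEMINI_12_6_12 = "CCCCCCCCCCCC[N+](C)(C)CCCCCC[N+](C)(C)CCCCCCCCCCCC"


@pytest.fixture(scope="session")
def training():
    return load_training()


@pytest.fixture(scope="session")
def test_set():
    return load_test()


@pytest.fixture(scope="session")
def structures():
    return load_structures()


@pytest.fixture(scope="session")
def gemini_12_6_12():
    return parse_smiles(GEMINI_12_6_12, name="C12C6C12")


@pytest.fixture(scope="session")
def small_random_molecules():
    """200 small random molecules for oracle cross-checks (<= 12 edges)."""
    cfg = SynthesisConfig(seed=1, n_atoms_min=4, n_atoms_max=9, ring_prob=0.3)
    rng = np.random.default_rng(20260901)
    return [random_molecule(cfg, rng) for _ in range(200)]
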