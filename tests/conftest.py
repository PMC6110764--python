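import numpy as np
import pytest

from rotpssm import PSSM, SyntheticConfig, generate_dataset, write_pssm


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def random_pssm(rng):
    """A 57-residue PSSM with scores in the realistic log-odds range."""
    scores = rng.integers(-10, 13, size=(57, 20))
    return PSSM(protein_id="prot57", scores=scores)


@pytest.fixture
def pssm_file(tmp_path, random_pssm):
    path = tmp_path / f"{random_pssm.protein_id}.pssm"
    write_pssm(random_pssm, path)
    return path


@pytest.fixture(scope="session")
def small_dataset():
    """Separable in-memory dataset small enough for per-test CV runs."""
    config = SyntheticConfig(
        n_proteins=40,
        n_pairs_per_class=40,
        length_range=(30, 60),
        separation=3.0,
        seed=11,
    )
    return generate_dataset(config)
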