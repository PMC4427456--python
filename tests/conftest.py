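import numpy as np
import pytest

from axoprot.synthetic import generate_proteome


@pytest.fixture(scope="session")
def small_proteome():
    """A 50-protein synthetic proteome with 3 isoform pairs, fixed seed."""
    return generate_proteome(n_proteins=50, n_isoform_pairs=3, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_sequence(rng, length):
    residues = "ACDEFGHIKLMNPQRSTVWY"
    return "".join(residues[i] for i in rng.integers(0, 20, size=length))
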