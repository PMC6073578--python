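import numpy as np
import pytest

from amylearn.sequence_io import AMINO_ACIDS, ProteinSequence


def random_protein(rng: np.random.Generator, length: int, ident: str = "seq") -> ProteinSequence:
    residues = "".join(rng.choice(list(AMINO_ACIDS), size=length))
    return ProteinSequence(ident, residues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def random_seqs(rng):
    """100 random sequences of lengths 2..120 for oracle comparisons."""
    return [
        random_protein(rng, int(rng.integers(2, 121)), f"r{i}") for i in range(100)
    ]
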