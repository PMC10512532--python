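import numpy as np
import pytest

from peptidestack.peptide_io import AMINO_ACIDS, LabeledDataset, Peptide
from peptidestack.synthetic import SynthConfig, generate


def random_peptide(rng, min_len=2, max_len=30, pid="p"):
    L = int(rng.integers(min_len, max_len + 1))
    seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
    return Peptide(pid, seq)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_peptides(rng):
    return [random_peptide(rng, pid=f"p{i}") for i in range(50)]


@pytest.fixture
def tiny_dataset():
    peptides = [
        Peptide("a", "ACDEFG"),
        Peptide("b", "GGGGCC"),
        Peptide("c", "YYWWRR"),
        Peptide("d", "LLPPDD"),
        Peptide("e", "MKTAYS"),
        Peptide("f", "QNHEVI"),
    ]
    return LabeledDataset(peptides, [1, 1, 1, 0, 0, 0], "tiny")


@pytest.fixture(scope="session")
def synth_300():
    """A 150+150 synthetic task at full signal, shared across tests."""
    return generate(SynthConfig(n_pos=150, n_neg=150, signal=1.0, seed=11))
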