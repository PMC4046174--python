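import numpy as np
import pytest
from hypothesis import settings

from mirfeat.rna_structures import ViennaRNABackend
from mirfeat.synthetic_data import (
    GeneratorParams,
    designed_backend,
    generate_dataset,
)

settings.register_profile("suite", deadline=None, derandomize=True,
                          max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_dataset():
    """25+25 designed records with structures and sidecar profiles."""
    params = GeneratorParams(n_pos=25, n_neg=25, seed=11)
    pos, neg = generate_dataset(params)
    return pos, neg


@pytest.fixture(scope="session")
def small_records(small_dataset):
    pos, neg = small_dataset
    return [sr.record for sr in pos + neg]


@pytest.fixture(scope="session")
def small_labels(small_dataset):
    pos, neg = small_dataset
    return np.array([sr.label for sr in pos + neg])


@pytest.fixture(scope="session")
def small_backend(small_dataset):
    pos, neg = small_dataset
    return designed_backend(pos + neg)


@pytest.fixture(scope="session")
def vienna_backend():
    return ViennaRNABackend()


@pytest.fixture(scope="session")
def dataset_files(tmp_path_factory, small_dataset):
    """The 25+25 dataset written to FASTA/Vienna/sidecar/labels files."""
    from mirfeat.synthetic_data import write_dataset

    pos, neg = small_dataset
    prefix = tmp_path_factory.mktemp("data") / "syn"
    return write_dataset(prefix, pos, neg)


def random_rna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=length))
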