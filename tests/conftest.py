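import numpy as np
import pytest

import codonopt as co
from codonopt.synthetic import SyntheticHostSpec, generate_gene_set, sample_host


@pytest.fixture(scope="session")
def code():
    return co.STANDARD_CODE


@pytest.fixture(scope="session")
def small_host():
    """A small markov-structured host shared by the slower module tests."""
    spec = SyntheticHostSpec(n_genes=10, mean_length=80, seed=11)
    data = generate_gene_set(spec, sample_host(spec))
    return data


@pytest.fixture(scope="session")
def small_refs(small_host):
    return (
        co.icu_distribution(small_host.genes),
        co.cc_distribution(small_host.genes),
    )


def make_seq(codons, **kw):
    return co.CodonSequence.from_codons(codons, **kw)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
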