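import numpy as np
import pytest

from utrlen.io import UTRRecord
from utrlen.simulate import TOY_SEQUENCES, make_toy_fixture, toy_expected_features


@pytest.fixture(scope="session")
def toy_dir(tmp_path_factory):
    """Directory holding the toy FASTA + expected-feature TSV."""
    d = tmp_path_factory.mktemp("toy")
    make_toy_fixture(d)
    return d


@pytest.fixture(scope="session")
def toy_fasta(toy_dir):
    return toy_dir / "toy_utrs.fasta"


@pytest.fixture(scope="session")
def toy_expected():
    return toy_expected_features()


@pytest.fixture(scope="session")
def toy_records():
    """The featurizable toy records (valid alphabet, length >= 3)."""
    return [
        UTRRecord(g, t, s)
        for g, t, s in TOY_SEQUENCES
        if set(s) <= set("ACGU") and len(s) >= 3
    ]


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)


def random_rna(rng, length, p=None):
    """Random RNA string with optional base probabilities [A, C, G, U]."""
    return "".join(rng.choice(list("ACGU"), size=length, p=p))
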