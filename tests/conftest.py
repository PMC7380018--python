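import numpy as np
import pytest

from chemogene import (
    SequenceRecord, load_reference_gene_table, load_reference_structure_table,
)


@pytest.fixture(scope="session")
def reference_genes():
    """The bundled published 18-gene OBP/CSP table."""
    return load_reference_gene_table()


@pytest.fixture(scope="session")
def reference_structure():
    """The bundled published intron/exon statistics (18 rows)."""
    return dict(load_reference_structure_table())


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_protein(rng, n, n_cys=None, alphabet="ADEFGHIKLMNPQRSTVWY"):
    """Random protein of length n with an exact number of cysteines planted
    at random positions (None = no constraint, C excluded)."""
    letters = np.array(list(alphabet))
    seq = list("".join(rng.choice(letters, size=n)))
    if n_cys:
        for pos in rng.choice(n, size=n_cys, replace=False):
            seq[pos] = "C"
    return "".join(seq)


def make_protein(seq, pid="p"):
    return SequenceRecord(pid, seq, "protein")
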