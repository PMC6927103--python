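import numpy as np
import pytest

from vaffp.model import ClonalTree, VAFMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def chain_F():
    """One sample, totally ordered frequencies 0.5 > 0.4 > 0.3."""
    return VAFMatrix([[0.5, 0.4, 0.3]], mutation_ids=["1", "2", "3"])


@pytest.fixture
def two_sample_F():
    """Mutations 2 and 3 incomparable across samples."""
    return VAFMatrix(
        [[0.5, 0.4, 0.3], [0.5, 0.3, 0.4]], mutation_ids=["1", "2", "3"]
    )


def chain(*labels):
    return ClonalTree.from_edges(list(zip(labels, labels[1:])))


def star(root, *leaves):
    return ClonalTree.from_edges([(root, leaf) for leaf in leaves])
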