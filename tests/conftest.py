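import numpy as np
import pytest

from sinephylo import (CharacterMatrix, Locus, RootedTree, TaxonPanel,
                       build_lemur_fixture, lemur_reference_tree)


@pytest.fixture(scope="session")
def lemur_matrix():
    return build_lemur_fixture()


@pytest.fixture(scope="session")
def lemur_tree():
    return lemur_reference_tree()


@pytest.fixture
def quartet_tree():
    """((A,B),(C,D)) with outgroup O attached at the root."""
    return RootedTree.from_newick("(((A,B),(C,D)),O);")


def make_matrix(taxa, columns, outgroups=(), ids=None):
    """Build a matrix from {taxon: state} column dicts (missing taxa = 0)."""
    taxa = tuple(taxa)
    states = np.zeros((len(taxa), len(columns)), dtype=np.int8)
    for j, col in enumerate(columns):
        for i, t in enumerate(taxa):
            states[i, j] = col.get(t, 0)
    ids = ids or [f"L{j+1}" for j in range(len(columns))]
    return CharacterMatrix(TaxonPanel(taxa, outgroups),
                           [Locus(i) for i in ids], states)


@pytest.fixture
def make_matrix_factory():
    return make_matrix
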