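import numpy as np
import pytest

from phylosel.alignment import CodonAlignment
from phylosel.codon_engine import CodonModelParams
from phylosel.genetics import N_SENSE
from phylosel.synthetic_data import default_species_tree
from phylosel.trees import PhyloTree


@pytest.fixture(scope="session")
def uniform_pi():
    return np.full(N_SENSE, 1.0 / N_SENSE)


@pytest.fixture(scope="session")
def random_pi():
    return np.random.default_rng(7).dirichlet(np.ones(N_SENSE))


@pytest.fixture()
def species_tree():
    return default_species_tree()


@pytest.fixture()
def three_taxon_tree():
    return PhyloTree.from_newick("(A:0.1,B:0.2,C:0.3);")


@pytest.fixture()
def tiny_alignment():
    return CodonAlignment(["A", "B", "C"], ["ATGAAA", "ATGAAC", "ATAAAC"])


@pytest.fixture()
def one_ratio_params(uniform_pi):
    return CodonModelParams(kappa=2.0, omega_map={"ALL": 0.3}, pi=uniform_pi)
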