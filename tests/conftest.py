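import numpy as np
import pytest

from dupsel.codon import CodonAlignment, standard_code
from dupsel.codonmodel import CodonModelParams, CodonModelSpec, fit
from dupsel.simulate import SimulationScenario, simulate_alignment
from dupsel.trees import PhyloTree


@pytest.fixture(scope="session")
def code():
    return standard_code()


@pytest.fixture(scope="session")
def equal_pi():
    return np.full(61, 1.0 / 61)


@pytest.fixture(scope="session")
def three_taxon_tree():
    return PhyloTree.from_newick("(A:0.2,B:0.3,C:0.25)anc;")


@pytest.fixture(scope="session")
def small_alignment():
    return CodonAlignment(ids=["A", "B", "C"], seqs=["AAATTG", "AACCTG", "GAATTA"])


@pytest.fixture(scope="session")
def m0_sim():
    """A moderate M0 simulation (4 taxa, 200 codons) shared across tests."""
    tree = PhyloTree.from_newick("((A:0.15,B:0.2)ab:0.1,C:0.25,D:0.12)root;")
    params = CodonModelParams(kappa=2.0, pi=np.full(61, 1.0 / 61), omega0=0.3)
    scen = SimulationScenario(tree=tree, params=params, n_codons=200, seed=11)
    aln, classes = simulate_alignment(scen)
    return {"tree": tree, "params": params, "aln": aln, "classes": classes}


@pytest.fixture(scope="session")
def m0_fit(m0_sim):
    return fit(m0_sim["aln"], m0_sim["tree"], CodonModelSpec("M0", "F3x4"),
               seed=1, n_starts=2)
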