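import numpy as np
import pytest
from hypothesis import settings

from kiwigenomics import CodonModelParams, PhyloTree, UNIVERSAL_CODE
from kiwigenomics.simulate import demo_bird_tree, simulate_codon_alignment

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def code():
    return UNIVERSAL_CODE


@pytest.fixture(scope="session")
def default_params():
    return CodonModelParams(kappa=2.0, omega_background=0.3)


@pytest.fixture(scope="session")
def star3():
    return PhyloTree.from_newick("(A:0.2,B:0.1,C:0.3);")


@pytest.fixture(scope="session")
def bird_tree():
    return demo_bird_tree()


@pytest.fixture(scope="session")
def bird_alignment(bird_tree, default_params):
    aln, truth = simulate_codon_alignment(bird_tree, default_params, 300, seed=11)
    return aln, truth
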