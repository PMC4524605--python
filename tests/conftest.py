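import pytest

from karyosynth.cytomap import SpeciesTree, load_fixture
from karyosynth.simulate import SimConfig, evolve


@pytest.fixture(scope="session")
def bundle():
    return load_fixture()


@pytest.fixture(scope="session")
def fixture_map(bundle):
    return bundle.cmap


@pytest.fixture(scope="session")
def karyotypes(bundle):
    return bundle.karyotypes


@pytest.fixture(scope="session")
def landmarks(bundle):
    return bundle.landmarks


@pytest.fixture(scope="session")
def tree(bundle):
    return bundle.tree


@pytest.fixture()
def sim_tree():
    return SpeciesTree("(OUT,(REF,SPA,SPB)Inner)Root;", outgroup="OUT")


def make_sim(tree, seed=0, **kwargs):
    defaults = dict(n_macro=8, n_micro=4, markers_per_macro=3, markers_per_micro=2)
    defaults.update(kwargs)
    return evolve(SimConfig(seed=seed, **defaults), tree)
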