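import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from sizehab.simulate import SimulationConfig, generate_dataset
from sizehab.tree import Phylogeny

from helpers import star_newick  # noqa: E402


@pytest.fixture
def cherry():
    return Phylogeny.from_newick("(A:1,B:1):0;")


@pytest.fixture
def three_tip():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2):0;")


@pytest.fixture
def balanced8():
    return Phylogeny.from_newick(
        "(((A:1,B:1):1,(C:1,D:1):1):1,((E:1,F:1):1,(G:1,H:1):1):1):0;"
    )


@pytest.fixture
def star20():
    return Phylogeny.from_newick(star_newick(20))


@pytest.fixture(scope="session")
def sim_result():
    """Medium synthetic dataset shared across test modules."""
    return generate_dataset(
        SimulationConfig(n_tips=150, seed=20, trophic_missing_frac=0.15)
    )


@pytest.fixture(scope="session")
def sim_dataset(sim_result):
    return sim_result.dataset
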