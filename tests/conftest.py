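import pytest

from pp2anet import DEFAULT_STRESSES, default_subunits
from pp2anet.synthetic_data import SyntheticSpec, generate_coexpression


@pytest.fixture
def stresses():
    return DEFAULT_STRESSES


@pytest.fixture
def subunits():
    return default_subunits()


@pytest.fixture
def small_table():
    """Full-coverage synthetic table with two planted hubs, all subunits."""
    spec = SyntheticSpec(
        n_genes=15, coverage=1.0, planted_hubs=("HUB1", "HUB2"), seed=42
    )
    table, truth = generate_coexpression(spec)
    return table, truth
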