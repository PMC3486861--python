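import numpy as np
import pytest

from chemevolve.chemistry import ChemistryRules
from chemevolve import fixtures


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(params=["polymer", "rearrangement", "aggregation"])
def any_rules(request):
    return ChemistryRules(kind=request.param, alphabet_size=2, max_length=4)


@pytest.fixture
def agg_rules():
    return ChemistryRules(kind="aggregation", alphabet_size=2, max_length=4)


@pytest.fixture(scope="session")
def abba_net():
    return fixtures.abba_reference_network()


@pytest.fixture(scope="session")
def abba_protocols():
    from chemevolve import tasks

    return tasks.gen_abba(np.random.default_rng(7), n_protocols=2)
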