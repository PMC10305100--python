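import pytest
from hypothesis import settings

import trialcea as t
from helpers import full_panel, make_trial

settings.register_profile("ci", deadline=None, max_examples=25, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def unit_costs():
    return t.default_unit_cost_table()


@pytest.fixture(scope="session")
def ledger():
    return t.default_programme_ledger()


@pytest.fixture(scope="session")
def trial_small():
    """30/30 participants, 2 sites, 10% dropout per occasion."""
    return make_trial(seed=7)


@pytest.fixture(scope="session")
def small_analysis(trial_small):
    """(complete_dataset, cost_panel) for the small trial."""
    return full_panel(trial_small)
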