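import dataclasses

import pytest

from trialcea import costing, synthetic


@pytest.fixture(scope="session")
def unit_costs():
    return costing.UnitCostTable.default()


@pytest.fixture(scope="session")
def default_config():
    return synthetic.TrialConfig(seed=1)


@pytest.fixture(scope="session")
def cohort(default_config):
    """Complete default-size cohort (263 participants), no missingness."""
    return synthetic.generate_cohort(default_config)


@pytest.fixture(scope="session")
def small_config():
    return dataclasses.replace(
        synthetic.TrialConfig(seed=42),
        n_per_arm={"CBT": 40, "PST": 40, "WL": 40})


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return synthetic.generate_cohort(small_config)
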