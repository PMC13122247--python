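import pytest

from gazemeta import (GeneratorConfig, assign_aq_group, filter_present_trials,
                      generate_dataset)


@pytest.fixture(scope="session")
def default_config():
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def dataset(default_config):
    """One default-size synthetic dataset shared across the session."""
    subjects, trials = generate_dataset(default_config)
    return assign_aq_group(subjects), trials


@pytest.fixture(scope="session")
def implicit_present(dataset):
    _, trials = dataset
    return filter_present_trials(
        trials[trials["task"] == "implicit"]).reset_index(drop=True)


@pytest.fixture(scope="session")
def explicit_trials(dataset):
    _, trials = dataset
    return trials[trials["task"] == "explicit"].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_config():
    """Reduced problem size for integration-style tests."""
    return GeneratorConfig(n_subjects=16, seed=11)
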