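import warnings

import pytest

from physioload import SimulationConfig, build_feature_table
from physioload.dataset import extract_features
from physioload.synth import generate_participant


@pytest.fixture(scope="session")
def default_config():
    return SimulationConfig()


@pytest.fixture(scope="session")
def default_table(default_config):
    """Full default study: 14 participants, 120 s segments, all streams."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return build_feature_table(default_config, seed=1)


@pytest.fixture(scope="session")
def one_participant(default_config):
    """A single participant's bundle and event log under default conditions."""
    return generate_participant(default_config, 1, seed=3)


@pytest.fixture(scope="session")
def p1_table_120(one_participant, default_config):
    bundle, events = one_participant
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_features(bundle, events, default_config, segment_length=120.0)


@pytest.fixture(scope="session")
def p1_table_30(one_participant, default_config):
    bundle, events = one_participant
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return extract_features(bundle, events, default_config, segment_length=30.0)
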