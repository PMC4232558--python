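import pytest

from phytoformula import (
    EnrichmentConfig,
    LayeredNetwork,
    load_default_config,
    load_fixture,
    load_rules,
    profile_table,
)


@pytest.fixture(scope="session")
def fixture_data():
    return load_fixture()


@pytest.fixture(scope="session")
def registry(fixture_data):
    return fixture_data[0]


@pytest.fixture(scope="session")
def structures(fixture_data):
    return fixture_data[1]


@pytest.fixture(scope="session")
def network(registry):
    return LayeredNetwork(registry)


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def profiles(structures, rules):
    return profile_table(structures, rules)


@pytest.fixture(scope="session")
def similarity_threshold():
    return float(load_default_config()["similarity_threshold"])


@pytest.fixture(scope="session")
def enrichment_config(similarity_threshold):
    return EnrichmentConfig(similarity_threshold=similarity_threshold)
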