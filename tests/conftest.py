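import pytest

from sedimet import ResuspensionScaling, load_flume_experiment


@pytest.fixture(scope="session")
def flume_table():
    """The packaged 32-treatment flume dataset with derived R_BIO."""
    table, _ = load_flume_experiment()
    return table


@pytest.fixture(scope="session")
def flume_model(flume_table):
    return ResuspensionScaling(flume_table)
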