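import pytest

from lectevo import io


@pytest.fixture(scope="session")
def kd_table():
    return io.load_packaged_kd_table()


@pytest.fixture(scope="session")
def printed_tables():
    return io.load_packaged_printed_table()


@pytest.fixture(scope="session")
def region_config():
    return io.load_packaged_region_config()


@pytest.fixture(scope="session")
def alignment():
    return io.load_packaged_sequences()


@pytest.fixture(scope="session")
def annotations():
    return io.load_glycan_annotations(io.packaged_path("glycan_annotations.yaml"))
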