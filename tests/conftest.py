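import pytest

from ovistage import load_staging_table


@pytest.fixture(scope="session")
def table():
    """The packaged canonical staging calibration."""
    return load_staging_table()
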