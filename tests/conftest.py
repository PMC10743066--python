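import pytest

from soyorigin import (
    load_default_panel,
    load_default_tables,
    load_standard_samples,
    load_standard_values,
)


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()


@pytest.fixture(scope="session")
def reference_tables():
    """The packaged 630-domestic / 466-imported discrimination tables."""
    return load_default_tables()


@pytest.fixture(scope="session")
def standards():
    """The 16 standard-variety profiles with their printed judgment values."""
    return load_standard_samples(), load_standard_values()
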