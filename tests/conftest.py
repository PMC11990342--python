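import pytest

from seedshield import core_io


@pytest.fixture(scope="session")
def fixtures():
    """Bundled printed-table fixtures, loaded once per session."""
    return core_io.load_fixtures()


@pytest.fixture(scope="session")
def film_e(fixtures):
    return fixtures.film_thickness_mm
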