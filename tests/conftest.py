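import pytest

from tatascreen import default_model, load_known_markers
from tatascreen.catalog import load_known_markers_frame


@pytest.fixture(scope="session")
def cfg():
    """The packaged default affinity model."""
    return default_model()


@pytest.fixture(scope="session")
def catalog():
    return load_known_markers()


@pytest.fixture(scope="session")
def catalog_frame():
    return load_known_markers_frame()
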