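import warnings

import pytest

from ramanlipids.fatty_acids import parse_fatty_acid, standard_registry


@pytest.fixture(scope="session")
def registry():
    return standard_registry()


@pytest.fixture(scope="session")
def oleic():
    return parse_fatty_acid("C18:1", 13.4)


@pytest.fixture(scope="session")
def palmitoleic():
    return parse_fatty_acid("C16:1", 0.5)


@pytest.fixture(scope="session")
def stearic():
    return parse_fatty_acid("C18:0", 69.3)


@pytest.fixture(autouse=True)
def _quiet_quality_warnings():
    """Silence routine fit-quality warnings; tests that assert on warnings
    use pytest.warns explicitly."""
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", category=UserWarning)
        yield
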