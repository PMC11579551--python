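import pytest

from mtminer.locate import default_profiles
from mtminer.reference import (
    default_catalog,
    default_reference,
    reference_self_fingerprint,
)


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture(scope="session")
def catalog(ref):
    return default_catalog(ref)


@pytest.fixture(scope="session")
def profiles():
    return default_profiles()


@pytest.fixture(scope="session")
def ref_fingerprint(ref):
    return reference_self_fingerprint(ref)
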