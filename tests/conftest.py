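import pytest

from herbcyp import load_reference_fixtures, profile_compound


@pytest.fixture(scope="session")
def fixtures():
    return load_reference_fixtures()


@pytest.fixture(scope="session")
def reference_profiles(fixtures):
    """Descriptor profiles of the packaged 12-compound set, keyed by id."""
    return {c.compound_id: profile_compound(c) for c in fixtures.compounds}
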