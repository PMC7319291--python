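import pytest

from degvar.io import fixture_catalogue


@pytest.fixture(scope="session")
def catalogue():
    """Deterministic named graph suite spanning every family."""
    return fixture_catalogue(seed=20260101)


@pytest.fixture(scope="session")
def star4():
    from degvar.generators import star_graph

    return star_graph(4)
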