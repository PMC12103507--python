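import pytest

from reduharm import fixtures, redu_schema, vocabulary


@pytest.fixture(scope="session")
def schema():
    return redu_schema.default_schema()


@pytest.fixture(scope="session")
def sheet():
    return vocabulary.load_default_sheet()


@pytest.fixture(scope="session")
def registries():
    return vocabulary.load_default_registries()


@pytest.fixture()
def demo_repo(tmp_path):
    """The three-study demo mini-repository plus its manifests."""
    root = tmp_path / "repo"
    manifests = fixtures.generate_demo_repository(root, seed=0)
    return root, manifests
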