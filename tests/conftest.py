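import json

import pytest

from exposource.fixtures import FixtureSpec, MockBackend, generate_fixtures
from exposource.retrieval import TransportError, fixture_adapters


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A 40-compound synthetic corpus shared across tests (read-only)."""
    directory = tmp_path_factory.mktemp("bundle")
    spec = FixtureSpec(n_compounds=40, seed=7)
    return generate_fixtures(spec, directory)


@pytest.fixture(scope="session")
def small_adapters(small_bundle):
    return fixture_adapters(small_bundle.corpus_dir)


@pytest.fixture
def mock_backend():
    return MockBackend()


class RecordingAdapter:
    """Stub adapter logging every lookup; payloads keyed by slug-insensitive term."""

    def __init__(self, payloads=None, fail=False):
        self.payloads = payloads or {}
        self.fail = fail
        self.lookups = []

    def lookup(self, term):
        self.lookups.append(term)
        if self.fail:
            raise TransportError("stubbed transport failure")
        return self.payloads.get(term)


@pytest.fixture
def recording_adapters():
    """Factory for an AdapterSet of recording stubs."""

    def _make(wiki=None, pubmed=None, synonyms=None, **kwargs):
        return (
            RecordingAdapter(wiki, **kwargs),
            RecordingAdapter(pubmed, **kwargs),
            RecordingAdapter(synonyms, **kwargs),
        )

    return _make


def make_corpus(root, wikipedia=(), pubmed=(), synonyms=()):
    """Write a hand-crafted fixture corpus; entries are (slug, payload)."""
    for sub, entries in (("wikipedia", wikipedia), ("pubmed", pubmed), ("synonyms", synonyms)):
        d = root / sub
        d.mkdir(parents=True, exist_ok=True)
        for slug, payload in entries:
            (d / f"{slug}.json").write_text(json.dumps(payload), encoding="utf-8")
    return root
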