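"""Name-based text retrieval for chemicals.

Evidence text for a compound is retrieved preferentially from Wikipedia body
text; PubMed abstracts (top 3 by the adapter's ranking) serve as the
alternative source when no Wikipedia page matches. When the compound's own
name misses everywhere, the query is expanded with up to five synonyms (e.g.
from PubChem) and the whole retrieval is repeated under each synonym. A
compound with no retrievable text yields an empty document, which downstream
classification maps to the fallback INFO label.

The cascade order is total and deterministic: Wikipedia is exhausted over the
name and every synonym before the first PubMed query. Synonym matches can be
semantically wrong for polysemous trade names (one string naming several
products), so every document records ``matched_term`` for provenance auditing.

All sources sit behind the :class:`TextSourceAdapter` protocol; the fixture
adapters read a local JSON corpus directory and need no network.
"""

from __future__ import annotations

import json
import logging
import re
import time
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Callable, Iterable, Protocol, Sequence

logger = logging.getLogger(__name__)

DEFAULT_CHAR_BUDGET = 50_000
DEFAULT_MAX_SYNONYMS = 5
DEFAULT_MAX_ABSTRACTS = 3
_RETRIES = 3


class Source(str, Enum):
    WIKIPEDIA = "WIKIPEDIA"
    PUBMED = "PUBMED"
    NONE = "NONE"


class TransportError(RuntimeError):
    """A retryable adapter failure (network, I/O) — distinct from a miss."""


class RetrievalError(RuntimeError):
    """Pipeline-level retrieval failure for a named compound."""

    def __init__(self, compound: str, message: str):
        self.compound = compound
        super().__init__(f"{compound}: {message}")


def slugify(name: str) -> str:
    """Corpus file key: lowercase with non-alphanumerics mapped to ``_``."""
    return re.sub(r"[^a-z0-9]", "_", name.strip().lower())


@dataclass(frozen=True)
class ChemicalQuery:
    """A compound name plus an ordered list of alternative names.

    Synonyms are deduplicated case-insensitively, never contain the name
    itself, and are truncated to ``max_synonyms``.
    """

    name: str
    synonyms: tuple[str, ...] = ()
    max_synonyms: int = DEFAULT_MAX_SYNONYMS

    def __post_init__(self) -> None:
        name = self.name.strip()
        if not name:
            raise ValueError("compound name must be non-empty")
        if self.max_synonyms < 1:
            raise ValueError("max_synonyms must be positive")
        object.__setattr__(self, "name", name)
        object.__setattr__(
            self,
            "synonyms",
            tuple(
                dedupe_synonyms(name, self.synonyms, self.max_synonyms)
            ),
        )


def dedupe_synonyms(name: str, synonyms: Iterable[str], k: int) -> list[str]:
    """First ``k`` synonyms in listed order, dropping blanks, case-insensitive
    duplicates and the query name itself."""
    seen = {name.strip().lower()}
    out: list[str] = []
    for syn in synonyms:
        syn = syn.strip()
        key = syn.lower()
        if not syn or key in seen:
            continue
        seen.add(key)
        out.append(syn)
        if len(out) == k:
            break
    return out


@dataclass(frozen=True)
class RetrievedDocument:
    """Text evidence for one compound with provenance.

    ``source`` is NONE iff ``text`` is empty; ``matched_term`` is the query
    string (name or synonym) that produced the hit; ``n_abstracts`` is
    non-zero only for PubMed documents.
    """

    compound: str
    source: Source
    text: str
    matched_term: str
    n_abstracts: int = 0

    def __post_init__(self) -> None:
        if (self.source is Source.NONE) != (self.text == ""):
            raise ValueError("source=NONE iff text is empty")
        if self.source is Source.PUBMED and not 1 <= self.n_abstracts:
            raise ValueError("PubMed document requires n_abstracts >= 1")
        if self.source is not Source.PUBMED and self.n_abstracts != 0:
            raise ValueError("n_abstracts must be 0 unless source=PUBMED")

    def to_json(self) -> str:
        return json.dumps(
            {
                "compound": self.compound,
                "source": self.source.value,
                "text": self.text,
                "matched_term": self.matched_term,
                "n_abstracts": self.n_abstracts,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, raw: str) -> "RetrievedDocument":
        d = json.loads(raw)
        return cls(
            compound=d["compound"],
            source=Source(d["source"]),
            text=d["text"],
            matched_term=d["matched_term"],
            n_abstracts=d["n_abstracts"],
        )


class TextSourceAdapter(Protocol):
    """Pluggable lookup of a raw payload by query term.

    Returns ``None`` on a miss; raises :class:`TransportError` on failure.
    The payload shape depends on the source: Wikipedia adapters return
    ``{"title": ..., "text": ...}``, PubMed adapters a list of abstract dicts
    in ranking order, synonym adapters a list of strings.
    """

    def lookup(self, term: str):  # pragma: no cover - protocol
        ...


# ---------------------------------------------------------------------------
# Text cleaning

_TAG_RE = re.compile(r"<[^>]+>")
_CITE_RE = re.compile(r"\[\s*(?:\d+|citation needed)\s*\]", re.IGNORECASE)
_HEADING_RE = re.compile(r"^\s*=+\s*(.*?)\s*=+\s*$", re.MULTILINE)
_REFS_RE = re.compile(
    r"(?:^|\n)\s*(references|external links|further reading|see also)\s*\n.*\Z",
    re.IGNORECASE | re.DOTALL,
)


def clean_text(text: str) -> str:
    """Minimal processing of raw page text.

    Strips markup tags and numeric citations, drops wiki-style section
    heading syntax, removes trailing reference/link sections and collapses
    all whitespace runs to single spaces. Idempotent.
    """
    text = _TAG_RE.sub(" ", text)
    text = _CITE_RE.sub(" ", text)
    text = _HEADING_RE.sub(r"\1\n", text)
    text = _REFS_RE.sub("\n", text)
    return re.sub(r"\s+", " ", text).strip()


def _with_retries(action: Callable[[], object], what: str):
    delay = 0.1
    for attempt in range(1, _RETRIES + 1):
        try:
            return action()
        except TransportError:
            if attempt == _RETRIES:
                raise
            logger.warning("transient failure on %s (attempt %d), retrying", what, attempt)
            time.sleep(delay)
            delay *= 2


# ---------------------------------------------------------------------------
# Single-source fetch operations


def fetch_wikipedia(
    term: str,
    adapter: TextSourceAdapter,
    *,
    compound: str | None = None,
    char_budget: int = DEFAULT_CHAR_BUDGET,
) -> RetrievedDocument | None:
    """Wikipedia body text for ``term``, cleaned and truncated, or ``None``."""
    if not term.strip():
        raise ValueError("term must be non-empty")
    page = _with_retries(lambda: adapter.lookup(term), f"wikipedia:{term}")
    if page is None:
        return None
    text = clean_text(page["text"])[:char_budget]
    if not text:
        return None
    return RetrievedDocument(
        compound=compound or term,
        source=Source.WIKIPEDIA,
        text=text,
        matched_term=term,
    )


def fetch_pubmed(
    term: str,
    adapter: TextSourceAdapter,
    *,
    k: int = DEFAULT_MAX_ABSTRACTS,
    compound: str | None = None,
    char_budget: int = DEFAULT_CHAR_BUDGET,
) -> RetrievedDocument | None:
    """Top ``k`` PubMed abstracts for ``term`` in the adapter's ranking
    order, concatenated with blank-line separators, or ``None`` on zero hits."""
    if not term.strip():
        raise ValueError("term must be non-empty")
    if k < 1:
        raise ValueError("k must be >= 1")
    abstracts = _with_retries(lambda: adapter.lookup(term), f"pubmed:{term}")
    if not abstracts:
        return None
    taken = list(abstracts)[:k]
    text = "\n\n".join(clean_text(a["text"]) for a in taken)[:char_budget]
    if not text.strip():
        return None
    return RetrievedDocument(
        compound=compound or term,
        source=Source.PUBMED,
        text=text,
        matched_term=term,
        n_abstracts=len(taken),
    )


def get_synonyms(
    name: str,
    adapter: TextSourceAdapter,
    *,
    k: int = DEFAULT_MAX_SYNONYMS,
) -> list[str]:
    """First ``k`` synonyms in the adapter's listed order, name excluded.

    Transport failures (after retries) degrade to an empty list with a
    logged warning — a missing synonym list must not abort a batch.
    """
    if not name.strip():
        raise ValueError("name must be non-empty")
    try:
        listed = _with_retries(lambda: adapter.lookup(name), f"synonyms:{name}")
    except TransportError:
        logger.warning("synonym lookup failed for %r; continuing without synonyms", name)
        return []
    if not listed:
        return []
    return dedupe_synonyms(name, listed, k)


# ---------------------------------------------------------------------------
# Cascade


@dataclass
class AdapterSet:
    """The three text sources consumed by the cascade."""

    wikipedia: TextSourceAdapter
    pubmed: TextSourceAdapter
    synonyms: TextSourceAdapter | None = None


def retrieve_cascade(
    query: ChemicalQuery,
    adapters: AdapterSet,
    *,
    char_budget: int = DEFAULT_CHAR_BUDGET,
    max_abstracts: int = DEFAULT_MAX_ABSTRACTS,
    cache: "RetrievalCache | None" = None,
) -> RetrievedDocument:
    """Resolve a compound name to evidence text via the retrieval cascade.

    Lookup order: Wikipedia(name), Wikipedia(each synonym in order),
    PubMed(name), PubMed(each synonym in order); the first hit wins and no
    later source is consulted. When every rung misses, the result has
    ``source=NONE`` and empty text (mapped to INFO downstream).

    Synonyms come from ``query.synonyms`` when supplied, otherwise from the
    synonym adapter (if configured).
    """
    if cache is not None:
        hit = cache.get(query.name)
        if hit is not None:
            return hit

    synonyms: Sequence[str] = query.synonyms
    if not synonyms and adapters.synonyms is not None:
        synonyms = get_synonyms(
            query.name, adapters.synonyms, k=query.max_synonyms
        )
    terms = [query.name, *synonyms]

    doc: RetrievedDocument | None = None
    try:
        for term in terms:
            doc = fetch_wikipedia(
                term, adapters.wikipedia, compound=query.name, char_budget=char_budget
            )
            if doc is not None:
                break
        if doc is None:
            for term in terms:
                doc = fetch_pubmed(
                    term,
                    adapters.pubmed,
                    k=max_abstracts,
                    compound=query.name,
                    char_budget=char_budget,
                )
                if doc is not None:
                    break
    except TransportError as exc:
        raise RetrievalError(query.name, f"retrieval failed: {exc}") from exc

    if doc is None:
        doc = RetrievedDocument(
            compound=query.name,
            source=Source.NONE,
            text="",
            matched_term=query.name,
        )
    if cache is not None:
        cache.put(doc)
    return doc


class RetrievalCache:
    """Cache of final cascade results keyed by compound name.

    In-memory always; mirrored to ``directory`` as one JSON file per
    compound when a directory is given, so batch re-runs are cheap and
    reproducible.
    """

    def __init__(self, directory: str | Path | None = None):
        self._mem: dict[str, str] = {}
        self._dir = Path(directory) if directory is not None else None
        if self._dir is not None:
            self._dir.mkdir(parents=True, exist_ok=True)

    def get(self, compound: str) -> RetrievedDocument | None:
        key = slugify(compound)
        raw = self._mem.get(key)
        if raw is None and self._dir is not None:
            path = self._dir / f"{key}.json"
            if path.exists():
                raw = path.read_text(encoding="utf-8")
                self._mem[key] = raw
        return RetrievedDocument.from_json(raw) if raw is not None else None

    def put(self, doc: RetrievedDocument) -> None:
        key = slugify(doc.compound)
        raw = doc.to_json()
        self._mem[key] = raw
        if self._dir is not None:
            (self._dir / f"{key}.json").write_text(raw, encoding="utf-8")


# ---------------------------------------------------------------------------
# Fixture corpus adapters

_WIKI_SUBDIR = "wikipedia"
_PUBMED_SUBDIR = "pubmed"
_SYNONYM_SUBDIR = "synonyms"


class FixtureWikipediaAdapter:
    """Wikipedia stand-in backed by ``<corpus>/wikipedia/<slug>.json`` files.

    Each file holds ``{"title", "text", "redirects": [...]}``; an optional
    ``"disambiguation": true`` marks a disambiguation page, which is treated
    as a miss (its listing text is not evidence about the chemical).
    Redirect titles resolve to their page. Deterministic, offline.
    """

    def __init__(self, corpus_dir: str | Path):
        self._index: dict[str, dict] = {}
        root = Path(corpus_dir) / _WIKI_SUBDIR
        for path in sorted(root.glob("*.json")) if root.is_dir() else []:
            page = json.loads(path.read_text(encoding="utf-8"))
            self._index[slugify(page["title"])] = page
            self._index.setdefault(path.stem, page)
            for redirect in page.get("redirects", []):
                self._index.setdefault(slugify(redirect), page)

    def lookup(self, term: str) -> dict | None:
        page = self._index.get(slugify(term))
        if page is None or page.get("disambiguation"):
            return None
        return page


class FixturePubMedAdapter:
    """PubMed stand-in backed by ``<corpus>/pubmed/<slug>.json`` files.

    Each file holds ``{"abstracts": [{"pmid", "title", "text"}, ...]}``;
    the list order is the fixture's declared relevance ranking and is
    returned unchanged.
    """

    def __init__(self, corpus_dir: str | Path):
        self._root = Path(corpus_dir) / _PUBMED_SUBDIR

    def lookup(self, term: str) -> list[dict] | None:
        path = self._root / f"{slugify(term)}.json"
        if not path.exists():
            return None
        return json.loads(path.read_text(encoding="utf-8"))["abstracts"]


class FixtureSynonymAdapter:
    """Synonym lists from ``<corpus>/synonyms/<slug>.json`` files."""

    def __init__(self, corpus_dir: str | Path):
        self._root = Path(corpus_dir) / _SYNONYM_SUBDIR

    def lookup(self, term: str) -> list[str] | None:
        path = self._root / f"{slugify(term)}.json"
        if not path.exists():
            return None
        return json.loads(path.read_text(encoding="utf-8"))["synonyms"]


def fixture_adapters(corpus_dir: str | Path) -> AdapterSet:
    """All three fixture adapters over one corpus directory."""
    return AdapterSet(
        wikipedia=FixtureWikipediaAdapter(corpus_dir),
        pubmed=FixturePubMedAdapter(corpus_dir),
        synonyms=FixtureSynonymAdapter(corpus_dir),
    )


# ---------------------------------------------------------------------------
# Batch output helpers


def write_documents_jsonl(docs: Iterable[RetrievedDocument], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(doc.to_json() + "\n")


def document_summary_rows(docs: Iterable[RetrievedDocument]) -> list[dict]:
    """Rows for the CSV summary (compound, source, matched_term, text_length)."""
    return [
        {
            "compound": d.compound,
            "source": d.source.value,
            "matched_term": d.matched_term,
            "text_length": len(d.text),
        }
        for d in docs
    ]
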