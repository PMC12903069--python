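"""Prompt construction, LLM backends and response parsing.

Classification works by appending retrieved evidence text to a structured
natural-language prompt and asking a language model to return the supported
exposure-source categories as a plain-text, comma-separated list (plain text
is more robust than structured formats like JSON for this task). The prompt
role-frames the model as a scientist, defines each category explicitly, and
repeatedly instructs the model to ground its answer solely in the provided
text; the fallback label INFO is offered for insufficient evidence.

The model response is normalized defensively: tokens are trimmed, uppercased
and matched against the active vocabulary, with single-token typos (edit
distance <= 2, unique match) repaired under a recorded warning — LLM output
occasionally contains misspellings such as "ENDOGENEOUS". A token that cannot
be matched raises a :class:`ParseError` rather than ever emitting a junk
label.

Backends are pluggable via the :class:`LLMBackend` protocol; temperature
defaults to 0 to promote deterministic output. The test suite and fixture
pipeline use only deterministic local backends.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from .labels import DEFAULT_VOCABULARY, INFO, LabelSet, levenshtein
from .retrieval import (
    AdapterSet,
    ChemicalQuery,
    RetrievalCache,
    RetrievedDocument,
    Source,
    retrieve_cascade,
)

logger = logging.getLogger(__name__)

#: Delimiter between the instruction block and the appended evidence text.
#: Everything after the *last* occurrence of this header is retrieved text.
EVIDENCE_HEADER = "Provided text:"

_FUZZY_MAX_DISTANCE = 2
REASK_INSTRUCTION = "Answer with only a comma-separated list of category names."


class ParseError(ValueError):
    """Model output could not be normalized into a valid label set."""

    def __init__(self, message: str, raw_response: str, token: str | None = None):
        self.raw_response = raw_response
        self.token = token
        super().__init__(message)


@dataclass(frozen=True)
class PromptSpec:
    """The structured, user-editable classification prompt.

    Rendering a prompt is a pure function of (spec, retrieved text): no
    clock, environment or randomness is consulted.
    """

    role_preamble: str
    categories: tuple[tuple[str, str], ...]  # ordered (NAME, definition)
    multi_label_instruction: str
    grounding_reminder: str
    output_instruction: str
    info_instruction: str

    def __post_init__(self) -> None:
        names = [name for name, _ in self.categories]
        if not names:
            raise ValueError("at least one category is required")
        if len(set(names)) != len(names):
            raise ValueError("category names must be unique")
        for name in names:
            if not name or name != name.upper():
                raise ValueError(f"category names must be non-empty uppercase: {name!r}")
        for fname in (
            "role_preamble",
            "multi_label_instruction",
            "grounding_reminder",
            "output_instruction",
            "info_instruction",
        ):
            if not getattr(self, fname).strip():
                raise ValueError(f"prompt component {fname} must be non-empty")

    @property
    def vocabulary(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.categories)

    def sha256(self) -> str:
        payload = json.dumps(
            {
                "role_preamble": self.role_preamble,
                "categories": list(self.categories),
                "multi_label_instruction": self.multi_label_instruction,
                "grounding_reminder": self.grounding_reminder,
                "output_instruction": self.output_instruction,
                "info_instruction": self.info_instruction,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode("utf-8")).hexdigest()


#: Default category definitions for exposomics source classification.
DEFAULT_CATEGORY_DEFINITIONS: tuple[tuple[str, str], ...] = (
    (
        "MEDICAL",
        "medications approved for human use or in late-stage clinical trials.",
    ),
    (
        "ENDOGENOUS",
        "compounds produced by the human body itself, excluding essential "
        "nutrients that cannot be synthesized internally.",
    ),
    (
        "FOOD",
        "naturally occurring food compounds and food additives.",
    ),
    (
        "PERSONAL CARE",
        "non-medicated compounds used in skincare, beauty, or fitness products.",
    ),
    (
        "INDUSTRIAL",
        "synthetic compounds not used in medical, food, or personal care "
        "contexts, such as plasticizers, pesticides, and polymer ingredients.",
    ),
)


def default_prompt_spec() -> PromptSpec:
    """The built-in exposomics prompt with the five default categories."""
    return PromptSpec(
        role_preamble=(
            "You are a scientist classifying the exposure sources of chemicals."
        ),
        categories=DEFAULT_CATEGORY_DEFINITIONS,
        multi_label_instruction=(
            "Examine the entire provided text and return every category "
            "supported by evidence in it; a compound may belong to several "
            "categories at once."
        ),
        grounding_reminder=(
            "Base your classification solely on the provided text. Do not use "
            "prior knowledge and do not make unsupported assumptions."
        ),
        output_instruction=(
            "Answer with a plain-text, comma-separated list of category names "
            "and nothing else."
        ),
        info_instruction=(
            "If the provided text lacks sufficient information for a confident "
            "classification, answer with the single word INFO."
        ),
    )


def build_prompt(spec: PromptSpec, doc: RetrievedDocument) -> str:
    """Render the full prompt: instructions first, evidence appended last.

    Raises ``ValueError`` on an empty document — callers must short-circuit
    empty retrievals to INFO instead of ever querying the model.
    """
    if not doc.text:
        raise ValueError(
            f"cannot build a prompt without evidence text for {doc.compound!r}"
        )
    lines = [
        spec.role_preamble,
        "",
        "Classify the chemical into the following categories:",
    ]
    lines += [f"- {name}: {definition}" for name, definition in spec.categories]
    lines += [
        "",
        spec.multi_label_instruction,
        spec.grounding_reminder,
        spec.info_instruction,
        spec.output_instruction,
        "",
        EVIDENCE_HEADER,
        doc.text,
    ]
    return "\n".join(lines)


class LLMBackend(Protocol):
    """A completion interface: prompt text in, raw response text out."""

    #: identifier recorded in classification provenance
    model: str

    def complete(self, prompt: str, temperature: float = 0.0) -> str:  # pragma: no cover
        ...


def _normalize_token(token: str) -> str:
    return token.strip().strip("'\"").rstrip(".").strip().upper()


def parse_response(
    raw: str,
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
) -> tuple[LabelSet, list[str]]:
    """Normalize a raw model response into a validated label set.

    Returns ``(labels, warnings)``. Splits on commas; trims whitespace,
    quotes and trailing periods; uppercases; exact-matches against the
    vocabulary plus INFO. A token within edit distance 2 of exactly one
    canonical label is repaired with a warning; INFO co-occurring with other
    labels is dropped with a warning.
    """
    warnings: list[str] = []
    canonical = list(vocabulary) + [INFO]
    tokens = [_normalize_token(t) for t in raw.split(",")]
    tokens = [t for t in tokens if t]
    if not tokens:
        raise ParseError("empty response", raw_response=raw)

    labels: set[str] = set()
    for token in tokens:
        if token in canonical:
            labels.add(token)
            continue
        near = [c for c in canonical if levenshtein(token, c) <= _FUZZY_MAX_DISTANCE]
        if len(near) == 1:
            warnings.append(f"fuzzy-corrected {token!r} -> {near[0]!r}")
            labels.add(near[0])
        else:
            reason = "ambiguous" if near else "unrecognized"
            raise ParseError(
                f"{reason} label token {token!r} in response {raw!r}",
                raw_response=raw,
                token=token,
            )

    if INFO in labels and len(labels) > 1:
        warnings.append("dropped INFO co-occurring with substantive labels")
        labels.discard(INFO)
    return LabelSet(frozenset(labels), tuple(vocabulary)), warnings


@dataclass(frozen=True)
class ClassificationRecord:
    """One compound's classification with full provenance."""

    compound: str
    source: Source
    labels: LabelSet
    raw_response: str
    matched_term: str
    model: str
    temperature: float = 0.0
    warnings: tuple[str, ...] = ()
    failed: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "compound": self.compound,
                "source": self.source.value,
                "labels": self.labels.in_canonical_order(),
                "raw_response": self.raw_response,
                "matched_term": self.matched_term,
                "model": self.model,
                "temperature": self.temperature,
                "warnings": list(self.warnings),
                "failed": self.failed,
            },
            sort_keys=True,
        )


def classify_one(
    query: ChemicalQuery,
    spec: PromptSpec,
    backend: LLMBackend,
    adapters: AdapterSet,
    *,
    temperature: float = 0.0,
    cache: RetrievalCache | None = None,
    char_budget: int = 50_000,
    max_abstracts: int = 3,
) -> ClassificationRecord:
    """Retrieve evidence for one compound and classify it.

    When retrieval finds nothing the record is {INFO} and the backend is
    never called. A parse failure triggers one automatic re-ask with a short
    format reminder; if that also fails to parse, the record is flagged
    ``failed`` with the raw response preserved and labels {INFO}.
    """
    doc = retrieve_cascade(
        query,
        adapters,
        cache=cache,
        char_budget=char_budget,
        max_abstracts=max_abstracts,
    )
    vocabulary = spec.vocabulary
    if doc.source is Source.NONE:
        return ClassificationRecord(
            compound=query.name,
            source=Source.NONE,
            labels=LabelSet.info(vocabulary),
            raw_response="",
            matched_term=doc.matched_term,
            model=backend.model,
            temperature=temperature,
        )

    prompt = build_prompt(spec, doc)
    raw = backend.complete(prompt, temperature=temperature)
    try:
        labels, warnings = parse_response(raw, vocabulary)
    except ParseError:
        reask = prompt + "\n\n" + REASK_INSTRUCTION
        raw = backend.complete(reask, temperature=temperature)
        try:
            labels, warnings = parse_response(raw, vocabulary)
        except ParseError as exc:
            logger.warning("unparseable response for %r: %s", query.name, exc)
            return ClassificationRecord(
                compound=query.name,
                source=doc.source,
                labels=LabelSet.info(vocabulary),
                raw_response=raw,
                matched_term=doc.matched_term,
                model=backend.model,
                temperature=temperature,
                warnings=(f"parse failed: {exc}",),
                failed=True,
            )
    if raw.strip() != labels.render() and not warnings:
        warnings.append("response normalized to canonical rendering")
    return ClassificationRecord(
        compound=query.name,
        source=doc.source,
        labels=labels,
        raw_response=raw,
        matched_term=doc.matched_term,
        model=backend.model,
        temperature=temperature,
        warnings=tuple(warnings),
    )


@dataclass
class BatchResult:
    records: list[ClassificationRecord]
    manifest: dict


def classify_batch(
    queries: Sequence[ChemicalQuery],
    spec: PromptSpec,
    backend: LLMBackend,
    adapters: AdapterSet,
    *,
    temperature: float = 0.0,
    cache: RetrievalCache | None = None,
    max_failure_fraction: float = 0.5,
) -> BatchResult:
    """Order-preserving batch classification with per-compound isolation.

    One compound's retrieval failure never aborts the batch below the
    configured failure fraction; failed compounds are recorded with
    ``failed=True`` and an INFO label.
    """
    if not queries:
        raise ValueError("no input: empty query list")
    records: list[ClassificationRecord] = []
    failures = 0
    for query in queries:
        try:
            rec = classify_one(
                query, spec, backend, adapters, temperature=temperature, cache=cache
            )
        except Exception as exc:  # retrieval transport after retries, etc.
            logger.error("classification failed for %r: %s", query.name, exc)
            rec = ClassificationRecord(
                compound=query.name,
                source=Source.NONE,
                labels=LabelSet.info(spec.vocabulary),
                raw_response="",
                matched_term=query.name,
                model=backend.model,
                temperature=temperature,
                warnings=(f"error: {exc}",),
                failed=True,
            )
        if rec.failed:
            failures += 1
            if failures / len(queries) > max_failure_fraction:
                raise RuntimeError(
                    f"aborting batch: {failures}/{len(queries)} compounds failed"
                )
        records.append(rec)

    by_source: dict[str, int] = {}
    by_label: dict[str, int] = {}
    for rec in records:
        by_source[rec.source.value] = by_source.get(rec.source.value, 0) + 1
        for label in rec.labels:
            by_label[label] = by_label.get(label, 0) + 1
    manifest = {
        "n_compounds": len(records),
        "n_failed": failures,
        "model": backend.model,
        "temperature": temperature,
        "prompt_sha256": spec.sha256(),
        "counts_by_source": dict(sorted(by_source.items())),
        "counts_by_label": dict(sorted(by_label.items())),
    }
    return BatchResult(records=records, manifest=manifest)


# ---------------------------------------------------------------------------
# PromptSpec file I/O


def load_prompt_spec(path: str | Path) -> PromptSpec:
    """Load a user-supplied prompt from a JSON or TOML file.

    Expected keys: role_preamble, categories (ordered name -> definition
    map), multi_label_instruction, grounding_reminder, output_instruction,
    info_instruction.
    """
    path = Path(path)
    if path.suffix.lower() == ".toml":
        import tomllib

        data = tomllib.loads(path.read_text(encoding="utf-8"))
    else:
        data = json.loads(path.read_text(encoding="utf-8"))
    categories = tuple((name.upper(), definition) for name, definition in data["categories"].items())
    return PromptSpec(
        role_preamble=data["role_preamble"],
        categories=categories,
        multi_label_instruction=data["multi_label_instruction"],
        grounding_reminder=data["grounding_reminder"],
        output_instruction=data["output_instruction"],
        info_instruction=data["info_instruction"],
    )


def write_records_jsonl(records: Iterable[ClassificationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(rec.to_json() + "\n")


def record_csv_rows(records: Iterable[ClassificationRecord]) -> list[dict]:
    """Rows for the CSV export (compound, ';'-joined labels, source, model)."""
    return [
        {
            "compound": r.compound,
            "labels": ";".join(r.labels.in_canonical_order()),
            "source": r.source.value,
            "model": r.model,
        }
        for r in records
    ]
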