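"""Seed-deterministic synthetic corpus and deterministic mock LLM backends.

The generator emits a toy knowledge corpus in the exact on-disk fixture
format the retrieval adapters consume, together with a ground-truth label
table, so the whole retrieve-prompt-classify pipeline can run end to end
offline with a known right answer. Each compound's document carries one
planted signal sentence per true category (containing an artificial token
such as ``SIGNAL_MEDICAL``); the keyword mock backend scans only the
evidence block of the prompt for those tokens, so recovering the truth table
exercises retrieval, prompt assembly, grounding and parsing — plumbing, not
natural-language understanding.

The generator reproduces the retrieval situations real batches encounter:
compounds findable only under a synonym, compounds with no encyclopedia page
but PubMed abstracts, and unretrievable compounds whose ground truth is the
INFO fallback. It does not attempt realistic chemistry prose, retrieval
ranking noise, or model reasoning failures beyond formatting perturbations
(see :class:`NoisyBackend`).
"""

from __future__ import annotations

import hashlib
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .labels import DEFAULT_VOCABULARY, INFO, LabelSet
from .prompting import EVIDENCE_HEADER, parse_response
from .retrieval import ChemicalQuery, slugify

_DEFAULT_MIX = {category: 0.18 for category in DEFAULT_VOCABULARY}


def signal_token(category: str) -> str:
    """The artificial evidence token planted for one category."""
    return "SIGNAL_" + category.replace(" ", "_")


_SENTENCE_TEMPLATES = (
    "Laboratory surveys of {name} repeatedly report the marker {token} in assay text.",
    "Technical notes describe {name} with the designation {token} in monographs.",
    "Catalog entries for {name} carry the indicator {token} among listed properties.",
)

_FILLER_SENTENCES = (
    "The compound is stable at room temperature and soluble in polar solvents.",
    "Commercial samples are distributed as a crystalline powder.",
    "Spectral reference data were deposited in a community library.",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic corpus.

    ``category_mix`` gives the probability of each primary category; the
    remainder to 1 is the unretrievable fraction (truth INFO, no corpus
    files). ``multi_label_rate`` is the chance a retrievable compound gains
    one or two extra categories; ``synonym_rate`` the share findable only
    under an alias; ``pubmed_only_rate`` the share with abstracts but no
    encyclopedia page.
    """

    n_compounds: int = 200
    seed: int = 0
    category_mix: Mapping[str, float] = field(default_factory=lambda: dict(_DEFAULT_MIX))
    multi_label_rate: float = 0.3
    synonym_rate: float = 0.2
    pubmed_only_rate: float = 0.2
    vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY

    def __post_init__(self) -> None:
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be >= 1")
        for rate_name in ("multi_label_rate", "synonym_rate", "pubmed_only_rate"):
            rate = getattr(self, rate_name)
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"{rate_name} must be in [0, 1], got {rate}")
        total = 0.0
        for category, p in self.category_mix.items():
            if category not in self.vocabulary:
                raise ValueError(f"category_mix names unknown category {category!r}")
            if p < 0:
                raise ValueError(f"negative probability for {category!r}")
            total += p
        if total > 1.0 + 1e-9:
            raise ValueError(f"category_mix probabilities sum to {total} > 1")
        if self.multi_label_rate > 0 and sum(p > 0 for p in self.category_mix.values()) < 2:
            raise ValueError(
                "multi_label_rate > 0 requires at least two categories with "
                "positive probability"
            )


@dataclass(frozen=True)
class FixtureBundle:
    """A generated corpus directory plus its ground truth and census."""

    corpus_dir: Path
    truth: Mapping[str, LabelSet]
    manifest: Mapping[str, object]

    def queries(self) -> list[ChemicalQuery]:
        """One query per compound, in generation order, without precomputed
        synonyms (the cascade consults the bundled synonym files)."""
        return [ChemicalQuery(name) for name in self.truth]

    def write_truth_csv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("compound,labels\n")
            for name, labels in self.truth.items():
                fh.write(f"{name},{';'.join(labels.in_canonical_order())}\n")


def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, sort_keys=True, indent=1), encoding="utf-8")


def generate_fixtures(spec: FixtureSpec, directory: str | Path) -> FixtureBundle:
    """Materialize a fixture corpus under ``directory``.

    Deterministic: the same spec and seed produce byte-identical files.
    """
    rng = random.Random(spec.seed)
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)

    categories = [c for c in spec.vocabulary if spec.category_mix.get(c, 0.0) > 0]
    cumulative: list[tuple[float, str]] = []
    acc = 0.0
    for category in categories:
        acc += spec.category_mix[category]
        cumulative.append((acc, category))

    truth: dict[str, LabelSet] = {}
    census = {category: 0 for category in spec.vocabulary}
    n_unretrievable = n_synonym_only = n_pubmed_only = 0

    for i in range(1, spec.n_compounds + 1):
        name = f"synthchem-{i:04d}"
        draw = rng.random()
        primary = next((c for bound, c in cumulative if draw < bound), None)
        if primary is None:
            truth[name] = LabelSet.info(spec.vocabulary)
            n_unretrievable += 1
            continue

        labels = {primary}
        if rng.random() < spec.multi_label_rate:
            others = [c for c in categories if c != primary]
            n_extra = min(rng.choice((1, 2)), len(others))
            labels.update(rng.sample(others, n_extra))
        truth[name] = LabelSet(frozenset(labels), spec.vocabulary)
        for category in labels:
            census[category] += 1

        synonym_only = rng.random() < spec.synonym_rate
        pubmed_only = rng.random() < spec.pubmed_only_rate
        corpus_term = name
        if synonym_only:
            n_synonym_only += 1
            corpus_term = f"alias-{name}"
            decoy = f"decoy-{name}"
            _write_json(
                root / "synonyms" / f"{slugify(name)}.json",
                {"name": name, "synonyms": [decoy, corpus_term]},
            )

        ordered = LabelSet(frozenset(labels), spec.vocabulary).in_canonical_order()
        sentences = [
            _SENTENCE_TEMPLATES[idx % len(_SENTENCE_TEMPLATES)].format(
                name=corpus_term, token=signal_token(category)
            )
            for idx, category in enumerate(ordered)
        ]
        filler = rng.choice(_FILLER_SENTENCES)

        if pubmed_only:
            n_pubmed_only += 1
            abstracts = [
                {
                    "pmid": f"{spec.seed}{i:06d}",
                    "title": f"A report on {corpus_term}",
                    "text": " ".join(sentences),
                },
                {
                    "pmid": f"{spec.seed}{i:06d}9",
                    "title": f"Further notes on {corpus_term}",
                    "text": filler,
                },
            ]
            _write_json(
                root / "pubmed" / f"{slugify(corpus_term)}.json",
                {"abstracts": abstracts},
            )
        else:
            _write_json(
                root / "wikipedia" / f"{slugify(corpus_term)}.json",
                {
                    "title": corpus_term,
                    "text": " ".join(sentences + [filler]),
                    "redirects": [],
                },
            )

    manifest = {
        "n_compounds": spec.n_compounds,
        "seed": spec.seed,
        "category_mix": dict(spec.category_mix),
        "multi_label_rate": spec.multi_label_rate,
        "synonym_rate": spec.synonym_rate,
        "pubmed_only_rate": spec.pubmed_only_rate,
        "census_by_category": census,
        "n_unretrievable": n_unretrievable,
        "n_synonym_only": n_synonym_only,
        "n_pubmed_only": n_pubmed_only,
    }
    _write_json(root / "manifest.json", manifest)
    return FixtureBundle(corpus_dir=root, truth=truth, manifest=manifest)


# ---------------------------------------------------------------------------
# Mock backends


class MockBackend:
    """Keyword-rule language model: reads only the evidence block.

    The response is the comma-separated list of categories whose signal
    token occurs after the last evidence header in the prompt, in canonical
    vocabulary order, or ``INFO`` when no token matches. Pure and
    deterministic.
    """

    model = "mock-keyword-v1"

    def __init__(self, vocabulary: Sequence[str] = DEFAULT_VOCABULARY):
        self.vocabulary = tuple(vocabulary)

    def complete(self, prompt: str, temperature: float = 0.0) -> str:
        _, _, evidence = prompt.rpartition(EVIDENCE_HEADER)
        found = [c for c in self.vocabulary if signal_token(c) in evidence]
        return ", ".join(found) if found else INFO


class CountingBackend:
    """Wrapper recording every call (used to assert grounding short-circuits
    and the default temperature)."""

    def __init__(self, base):
        self.base = base
        self.calls: list[tuple[str, float]] = []

    @property
    def model(self) -> str:
        return self.base.model

    def complete(self, prompt: str, temperature: float = 0.0) -> str:
        self.calls.append((prompt, temperature))
        return self.base.complete(prompt, temperature=temperature)

    @property
    def call_count(self) -> int:
        return len(self.calls)


class NoisyBackend:
    """Formatting-noise wrapper emulating LLM output quirks.

    Perturbs each label token of the base response with probability
    ``typo_rate``: case changes, stray whitespace, trailing periods, and
    single-character duplications/deletions. Every perturbation is verified
    to remain uniquely recoverable by the response parser before being
    emitted, so noise tests exercise robustness, not ambiguity. Deterministic
    given (seed, prompt).
    """

    def __init__(
        self,
        base,
        typo_rate: float,
        seed: int,
        vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
    ):
        if not 0.0 <= typo_rate <= 1.0:
            raise ValueError("typo_rate must be in [0, 1]")
        self.base = base
        self.typo_rate = typo_rate
        self.seed = seed
        self.vocabulary = tuple(vocabulary)

    @property
    def model(self) -> str:
        return f"{self.base.model}+noise"

    def _recoverable(self, perturbed: str, original: str) -> bool:
        try:
            labels, _ = parse_response(perturbed, self.vocabulary)
        except Exception:
            return False
        return labels.labels == {original}

    def _perturb_token(self, token: str, rng: random.Random) -> str:
        candidates = []
        # order shuffled per token for variety; all edits are small
        edits = ["case", "dup", "del", "pad", "period"]
        rng.shuffle(edits)
        for edit in edits:
            if edit == "case":
                candidates.append(token.lower())
            elif edit == "dup" and token:
                i = rng.randrange(len(token))
                candidates.append(token[:i] + token[i] + token[i:])
            elif edit == "del" and len(token) > 2:
                i = rng.randrange(len(token))
                candidates.append(token[:i] + token[i + 1 :])
            elif edit == "pad":
                candidates.append(f"  {token} ")
            elif edit == "period":
                candidates.append(token + ".")
        for candidate in candidates:
            if candidate != token and self._recoverable(candidate, token):
                return candidate
        return token

    def complete(self, prompt: str, temperature: float = 0.0) -> str:
        raw = self.base.complete(prompt, temperature=temperature)
        digest = hashlib.sha256(f"{self.seed}:{prompt}".encode("utf-8")).digest()
        rng = random.Random(int.from_bytes(digest[:8], "big"))
        tokens = [t.strip() for t in raw.split(",")]
        out = []
        for token in tokens:
            if rng.random() < self.typo_rate:
                out.append(self._perturb_token(token, rng))
            else:
                out.append(token)
        return ", ".join(out)
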