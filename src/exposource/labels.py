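"""Exposure-source label vocabulary and validated label sets.

The default vocabulary holds the five exposure-relevant categories used for
exposomics work — MEDICAL, ENDOGENOUS, FOOD, PERSONAL CARE and INDUSTRIAL —
plus the reserved fallback label INFO, assigned when no classification-relevant
evidence is available. INFO is exclusive: it never co-occurs with a substantive
category in a valid :class:`LabelSet`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

#: Canonical category order. Used for deterministic rendering everywhere
#: (mock backend output, CSV serialization, prompt definition blocks).
DEFAULT_VOCABULARY: tuple[str, ...] = (
    "MEDICAL",
    "ENDOGENOUS",
    "FOOD",
    "PERSONAL CARE",
    "INDUSTRIAL",
)

#: Fallback label emitted when no evidence supports any category.
INFO = "INFO"


class LabelError(ValueError):
    """Raised when a label set violates the vocabulary contract."""


@dataclass(frozen=True)
class LabelSet:
    """A validated, non-empty set of exposure-source labels.

    Invariants enforced at construction:

    * non-empty;
    * if INFO is present it is the only member;
    * every member belongs to ``vocabulary`` (default: the five exposure
      categories) or is INFO.
    """

    labels: frozenset[str]
    vocabulary: tuple[str, ...] = field(default=DEFAULT_VOCABULARY, compare=False)

    def __post_init__(self) -> None:
        labels = frozenset(self.labels)
        object.__setattr__(self, "labels", labels)
        if not labels:
            raise LabelError("label set must be non-empty")
        if INFO in labels and len(labels) > 1:
            raise LabelError(f"INFO is exclusive but got {sorted(labels)}")
        allowed = set(self.vocabulary) | {INFO}
        unknown = labels - allowed
        if unknown:
            raise LabelError(
                f"labels outside vocabulary {sorted(allowed)}: {sorted(unknown)}"
            )

    @classmethod
    def of(cls, *labels: str, vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY) -> "LabelSet":
        return cls(frozenset(labels), vocabulary)

    @classmethod
    def info(cls, vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY) -> "LabelSet":
        return cls(frozenset({INFO}), vocabulary)

    @property
    def is_info(self) -> bool:
        return self.labels == {INFO}

    def in_canonical_order(self) -> list[str]:
        """Members sorted by vocabulary position (INFO last)."""
        order = {name: i for i, name in enumerate(self.vocabulary)}
        return sorted(self.labels, key=lambda l: (order.get(l, len(order)), l))

    def render(self) -> str:
        """Canonical comma-separated rendering, e.g. ``"MEDICAL, INDUSTRIAL"``."""
        return ", ".join(self.in_canonical_order())

    def __contains__(self, label: str) -> bool:
        return label in self.labels

    def __iter__(self) -> Iterator[str]:
        return iter(self.in_canonical_order())

    def __len__(self) -> int:
        return len(self.labels)


def parse_label_field(text: str, vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY) -> LabelSet:
    """Parse a ``;``- or ``,``-joined label field from a CSV cell."""
    sep = ";" if ";" in text else ","
    tokens = [t.strip().upper() for t in text.split(sep) if t.strip()]
    if not tokens:
        raise LabelError(f"empty label field: {text!r}")
    return LabelSet(frozenset(tokens), vocabulary)


def render_labels(labels: Iterable[str], vocabulary: tuple[str, ...] = DEFAULT_VOCABULARY) -> str:
    return LabelSet(frozenset(labels), vocabulary).render()


def levenshtein(a: str, b: str) -> int:
    """Edit distance (insert/delete/substitute), used for fuzzy label repair."""
    if len(a) < len(b):
        a, b = b, a
    previous = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        current = [i]
        for j, cb in enumerate(b, start=1):
            current.append(
                min(
                    previous[j] + 1,
                    current[j - 1] + 1,
                    previous[j - 1] + (ca != cb),
                )
            )
        previous = current
    return previous[-1]
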