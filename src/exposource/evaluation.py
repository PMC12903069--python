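"""Multi-label benchmark metrics against reference annotations.

Predicted label sets are compared with manually curated reference label sets
per compound. Agreement is measured as the exact-set match fraction plus the
distribution of symmetric set-difference sizes (how many category labels a
pair differs by), and per category as precision, recall and F1 computed over
label-set membership: for category *c*,

    TP = #{pairs with c in both reference and predicted}
    FP = #{pairs with c only in predicted}
    FN = #{pairs with c only in reference}
    precision = TP/(TP+FP),  recall = TP/(TP+FN),  F1 = 2PR/(P+R)

A zero denominator leaves the metric undefined (``None``), never silently
zero — a category with no predictions has no precision, and averaging over
silently zero-filled rows would deflate the summary.

Because an INFO prediction carries no substantive claim, benchmark pairs with
an INFO prediction are excluded by default (mirroring benchmarks that report
metrics over the classified subset only); ``include_info=True`` instead keeps
them, counting INFO as an empty prediction that disagrees with any reference.

``strip_category`` supports the deflation analysis where one dominant
category (e.g. a MEDICAL label attached to every compound in a drug library)
is removed from both sides before re-computing agreement.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .labels import DEFAULT_VOCABULARY, INFO, LabelSet


@dataclass(frozen=True)
class BenchmarkPair:
    """(reference, predicted) label sets for one compound.

    ``predicted=None`` is the designated no-substantive-prediction marker
    produced by :func:`strip_category`; it disagrees with every reference.
    The reference is always substantive (manual labels never contain INFO).
    """

    compound: str
    reference: LabelSet
    predicted: LabelSet | None

    def __post_init__(self) -> None:
        if INFO in self.reference:
            raise ValueError(
                f"reference labels for {self.compound!r} must not contain INFO"
            )

    def _predicted_set(self) -> frozenset[str]:
        if self.predicted is None or self.predicted.is_info:
            return frozenset()
        return self.predicted.labels

    @property
    def difference(self) -> int:
        """Size of the symmetric difference between reference and predicted."""
        return len(self.reference.labels ^ self._predicted_set())


@dataclass(frozen=True)
class CategoryMetrics:
    category: str
    tp: int
    fp: int
    fn: int
    precision: float | None
    recall: float | None
    f1: float | None


@dataclass(frozen=True)
class MetricsTable:
    """Per-category metrics plus overall agreement statistics."""

    per_category: tuple[CategoryMetrics, ...]
    exact_agreement: float
    difference_histogram: Mapping[int, float]
    n_pairs: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "category": m.category,
                    "TP": m.tp,
                    "FP": m.fp,
                    "FN": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
                for m in self.per_category
            ]
        )

    def to_dict(self) -> dict:
        return {
            "n_pairs": self.n_pairs,
            "exact_agreement": self.exact_agreement,
            "difference_histogram": {str(k): v for k, v in sorted(self.difference_histogram.items())},
            "per_category": [
                {
                    "category": m.category,
                    "TP": m.tp,
                    "FP": m.fp,
                    "FN": m.fn,
                    "precision": m.precision,
                    "recall": m.recall,
                    "f1": m.f1,
                }
                for m in self.per_category
            ],
        }

    def category(self, name: str) -> CategoryMetrics:
        for m in self.per_category:
            if m.category == name:
                return m
        raise KeyError(name)


def _validate_pairs(
    pairs: Sequence[BenchmarkPair], vocabulary: Sequence[str]
) -> None:
    if not pairs:
        raise ValueError("at least one benchmark pair is required")
    seen: set[str] = set()
    allowed = set(vocabulary) | {INFO}
    for pair in pairs:
        if pair.compound in seen:
            raise ValueError(f"duplicate compound in benchmark: {pair.compound!r}")
        seen.add(pair.compound)
        for side, labels in (("reference", pair.reference), ("predicted", pair.predicted)):
            if labels is None:
                continue
            extra = labels.labels - allowed
            if extra:
                raise ValueError(
                    f"{side} labels of {pair.compound!r} outside vocabulary: {sorted(extra)}"
                )


def _filter_info(
    pairs: Sequence[BenchmarkPair], include_info: bool
) -> list[BenchmarkPair]:
    if include_info:
        return list(pairs)
    kept = [
        p
        for p in pairs
        if p.predicted is not None and not p.predicted.is_info
    ]
    if not kept:
        raise ValueError("all predictions are INFO; nothing to evaluate")
    return kept


def per_category_metrics(
    pairs: Sequence[BenchmarkPair],
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
    *,
    include_info: bool = False,
) -> MetricsTable:
    """Precision, recall and F1 per category, plus overall agreement."""
    _validate_pairs(pairs, vocabulary)
    kept = _filter_info(pairs, include_info)

    rows = []
    for category in vocabulary:
        tp = fp = fn = 0
        for pair in kept:
            in_ref = category in pair.reference
            in_pred = category in pair._predicted_set()
            tp += in_ref and in_pred
            fp += in_pred and not in_ref
            fn += in_ref and not in_pred
        precision = tp / (tp + fp) if tp + fp else None
        recall = tp / (tp + fn) if tp + fn else None
        if precision is None or recall is None or precision + recall == 0:
            f1 = None if precision is None or recall is None else 0.0
        else:
            f1 = 2 * precision * recall / (precision + recall)
        rows.append(
            CategoryMetrics(
                category=category, tp=tp, fp=fp, fn=fn,
                precision=precision, recall=recall, f1=f1,
            )
        )

    exact, histogram = agreement_and_difference(kept, include_info=True)
    return MetricsTable(
        per_category=tuple(rows),
        exact_agreement=exact,
        difference_histogram=histogram,
        n_pairs=len(kept),
    )


def agreement_and_difference(
    pairs: Sequence[BenchmarkPair],
    *,
    include_info: bool = True,
) -> tuple[float, dict[int, float]]:
    """Exact-match fraction and histogram over symmetric-difference sizes.

    The histogram maps k (number of differing category labels) to the
    fraction of compounds; fractions sum to 1 and histogram[0] equals the
    exact-agreement fraction. Symmetric in (reference, predicted).
    """
    if not pairs:
        raise ValueError("at least one benchmark pair is required")
    kept = _filter_info(pairs, include_info)
    counts = Counter(p.difference for p in kept)
    n = len(kept)
    histogram = {k: counts[k] / n for k in sorted(counts)}
    return histogram.get(0, 0.0), histogram


def strip_category(
    pairs: Sequence[BenchmarkPair],
    category: str,
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
) -> list[BenchmarkPair]:
    """Remove one category from both sides of every pair.

    A pair whose reference becomes empty is dropped (no substantive
    reference left to judge). A predicted set that becomes empty turns into
    the ``None`` marker and counts as a disagreement with any reference.
    """
    if category not in vocabulary:
        raise ValueError(f"{category!r} is not in the vocabulary")
    out: list[BenchmarkPair] = []
    for pair in pairs:
        ref = pair.reference.labels - {category}
        if not ref:
            continue
        pred: LabelSet | None
        if pair.predicted is None:
            pred = None
        else:
            remaining = pair._predicted_set() - {category}
            pred = LabelSet(frozenset(remaining), tuple(vocabulary)) if remaining else None
        out.append(
            BenchmarkPair(
                compound=pair.compound,
                reference=LabelSet(frozenset(ref), tuple(vocabulary)),
                predicted=pred,
            )
        )
    return out


@dataclass(frozen=True)
class ReproducibilityReport:
    """Per-compound label stability across repeated classification runs."""

    n_runs: int
    counts: Mapping[str, Mapping[str, int]]  # compound -> label -> count
    focal_label: str

    def rate(self, compound: str) -> float:
        """Occurrence rate of the focal label for one compound."""
        return self.counts[compound].get(self.focal_label, 0) / self.n_runs

    def rates(self) -> dict[str, float]:
        return {c: self.rate(c) for c in self.counts}

    def n_always(self) -> int:
        """Compounds carrying the focal label in every run."""
        return sum(1 for c in self.counts if self.rate(c) == 1.0)


def reproducibility(
    runs: Mapping[str, Sequence[LabelSet]],
    focal_label: str,
) -> ReproducibilityReport:
    """Per-label occurrence counts over repeated runs of the same compounds.

    ``runs`` maps each compound to its per-run label sets; every compound
    must have the same positive number of runs.
    """
    if not runs:
        raise ValueError("no runs supplied")
    lengths = {len(v) for v in runs.values()}
    if len(lengths) != 1 or 0 in lengths:
        raise ValueError(f"all compounds need the same positive run count, got {sorted(lengths)}")
    n_runs = lengths.pop()
    counts = {
        compound: dict(Counter(label for labels in run_list for label in labels))
        for compound, run_list in runs.items()
    }
    return ReproducibilityReport(n_runs=n_runs, counts=counts, focal_label=focal_label)


def harmonize_vocabulary(
    labels: LabelSet,
    mapping: Mapping[str, str],
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
) -> LabelSet:
    """Map labels from an external use-category ontology onto the canonical
    vocabulary; the image is deduplicated. Unmapped terms are an error."""
    unmapped = [l for l in labels.labels if l not in mapping]
    if unmapped:
        raise ValueError(f"unmapped external terms: {sorted(unmapped)}")
    image = {mapping[l] for l in labels.labels}
    outside = image - set(vocabulary) - {INFO}
    if outside:
        raise ValueError(f"mapping targets outside canonical vocabulary: {sorted(outside)}")
    return LabelSet(frozenset(image), tuple(vocabulary))


# ---------------------------------------------------------------------------
# Table I/O


def pairs_from_tables(
    reference: pd.DataFrame,
    predicted: pd.DataFrame,
    vocabulary: Sequence[str] = DEFAULT_VOCABULARY,
) -> list[BenchmarkPair]:
    """Join reference and prediction tables (columns: compound, labels) on
    compound name; labels are ';'- or ','-joined. Missing keys are an error.

    Reference rows labeled INFO carry no substantive annotation and are
    skipped — a benchmark reference is always a real label set.
    """
    from .labels import parse_label_field

    ref_map = dict(zip(reference["compound"], reference["labels"]))
    pred_map = dict(zip(predicted["compound"], predicted["labels"]))
    missing = sorted(set(ref_map) - set(pred_map))
    if missing:
        raise ValueError(f"compounds missing from predictions: {missing[:5]}")
    vocab = tuple(vocabulary)
    pairs = []
    for compound in ref_map:
        ref = parse_label_field(str(ref_map[compound]), vocab)
        if ref.is_info:
            continue
        pairs.append(
            BenchmarkPair(
                compound=compound,
                reference=ref,
                predicted=parse_label_field(str(pred_map[compound]), vocab),
            )
        )
    return pairs
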