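"""Context-based label refinement and exposure-source profiles.

A compound legitimately used in several domains (e.g. phenylalanine: FOOD,
MEDICAL and PERSONAL CARE) over-represents the minor domains when summed
into a dataset-level profile. Refinement resolves multi-label assignments
using what the sample type makes plausible:

* BIOSPECIMEN (plasma, feces, tissue): a multi-label set containing
  ENDOGENOUS and/or FOOD is reduced to its ENDOGENOUS/FOOD part — such
  compounds can be sourced from host metabolism or diet.
* FOOD_EXTRACT: a multi-label set containing FOOD becomes FOOD-only.
* PRODUCT_OR_SURFACE (consumer product extracts, surface swabs): only
  PERSONAL CARE and/or INDUSTRIAL labels are retained — detected compounds
  are likely direct additives.
* NONE: no refinement (e.g. environmental dust with no dominant expected
  source).

Single-label sets are never modified and refinement never empties a set or
invents a label.

The exposure profile of a dataset is the detection-frequency-weighted
distribution over source categories: each category's raw mass is the sum of
detection frequencies of compounds carrying that label (a multi-label
compound contributes its full frequency to each of its categories), and the
masses are sum-normalized to 1. INFO rows carry no source evidence and are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping

import pandas as pd

from .labels import DEFAULT_VOCABULARY, LabelSet

_NORM_TOL = 1e-9


class SampleContext(str, Enum):
    BIOSPECIMEN = "BIOSPECIMEN"
    FOOD_EXTRACT = "FOOD_EXTRACT"
    PRODUCT_OR_SURFACE = "PRODUCT_OR_SURFACE"
    NONE = "NONE"


_BIO_KEEP = frozenset({"ENDOGENOUS", "FOOD"})
_PRODUCT_KEEP = frozenset({"PERSONAL CARE", "INDUSTRIAL"})


def refine_labels(labels: LabelSet, context: SampleContext) -> LabelSet:
    """Apply the context rule for one compound; identity for singletons,
    INFO, context NONE, or when the context's keep-set is absent."""
    if len(labels) <= 1 or context is SampleContext.NONE:
        return labels
    members = labels.labels
    if context is SampleContext.BIOSPECIMEN:
        kept = members & _BIO_KEEP
    elif context is SampleContext.FOOD_EXTRACT:
        kept = frozenset({"FOOD"}) if "FOOD" in members else frozenset()
    elif context is SampleContext.PRODUCT_OR_SURFACE:
        kept = members & _PRODUCT_KEEP
    else:  # pragma: no cover - enum is exhaustive
        raise AssertionError(context)
    if not kept:
        return labels
    return LabelSet(kept, labels.vocabulary)


@dataclass(frozen=True)
class AnnotationRow:
    compound: str
    labels: LabelSet
    detection_frequency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.detection_frequency <= 1.0:
            raise ValueError(
                f"detection frequency of {self.compound!r} outside [0, 1]: "
                f"{self.detection_frequency}"
            )


@dataclass(frozen=True)
class AnnotationTable:
    """Annotated compounds of one dataset with per-compound detection
    frequency (fraction of samples in which the compound is observed)."""

    rows: tuple[AnnotationRow, ...]

    def __post_init__(self) -> None:
        names = [r.compound for r in self.rows]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate compounds in annotation table: {dupes}")

    def refined(self, context: SampleContext) -> "AnnotationTable":
        return AnnotationTable(
            tuple(
                AnnotationRow(r.compound, refine_labels(r.labels, context), r.detection_frequency)
                for r in self.rows
            )
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, vocabulary=DEFAULT_VOCABULARY) -> "AnnotationTable":
        """Build from a DataFrame with columns compound, labels (';'-joined),
        detection_frequency."""
        from .labels import parse_label_field

        return cls(
            tuple(
                AnnotationRow(
                    compound=str(row["compound"]),
                    labels=parse_label_field(str(row["labels"]), tuple(vocabulary)),
                    detection_frequency=float(row["detection_frequency"]),
                )
                for _, row in frame.iterrows()
            )
        )


@dataclass(frozen=True)
class ExposureProfile:
    """Sum-normalized relative abundance per source category."""

    abundances: Mapping[str, float]
    n_excluded_info: int = 0

    def __post_init__(self) -> None:
        total = sum(self.abundances.values())
        if abs(total - 1.0) > _NORM_TOL:
            raise ValueError(f"profile must sum to 1, got {total}")
        if any(v < 0 for v in self.abundances.values()):
            raise ValueError("abundances must be non-negative")

    def __getitem__(self, category: str) -> float:
        return self.abundances.get(category, 0.0)


def compute_profile(table: AnnotationTable, *, split_frequency: bool = False) -> ExposureProfile:
    """Detection-frequency-weighted, sum-normalized source distribution.

    By default a multi-label compound credits its full detection frequency to
    each of its categories; with ``split_frequency`` the frequency is divided
    evenly among them (a sensitivity-analysis mode). Raises when no row
    carries a substantive label with positive frequency.
    """
    raw: dict[str, float] = {}
    excluded = 0
    for row in table.rows:
        if row.labels.is_info:
            excluded += 1
            continue
        weight = row.detection_frequency / (len(row.labels) if split_frequency else 1)
        for label in row.labels:
            raw[label] = raw.get(label, 0.0) + weight
    total = sum(raw.values())
    if total <= 0:
        raise ValueError("no classifiable signal: all rows INFO or zero-frequency")
    return ExposureProfile(
        abundances={c: v / total for c, v in sorted(raw.items())},
        n_excluded_info=excluded,
    )


@dataclass(frozen=True)
class DatasetProfiles:
    raw: Mapping[str, ExposureProfile]
    refined: Mapping[str, ExposureProfile]
    refined_tables: Mapping[str, AnnotationTable]
    errors: Mapping[str, str] = field(default_factory=dict)

    def to_long_frame(self) -> pd.DataFrame:
        """Long-format table (dataset, category, relative_abundance, stage)."""
        records = []
        for stage, profiles in (("raw", self.raw), ("refined", self.refined)):
            for dataset, profile in profiles.items():
                for category, abundance in profile.abundances.items():
                    records.append(
                        {
                            "dataset": dataset,
                            "category": category,
                            "relative_abundance": abundance,
                            "stage": stage,
                        }
                    )
        return pd.DataFrame(records)


def profile_datasets(
    tables: Mapping[str, AnnotationTable],
    contexts: Mapping[str, SampleContext] | None = None,
) -> DatasetProfiles:
    """Per-dataset profiles before and after context refinement.

    Datasets without a configured context default to NONE. Per-dataset
    failures (e.g. an all-INFO table) are isolated and reported in
    ``errors`` rather than aborting the run.
    """
    if not tables:
        raise ValueError("no input: empty dataset map")
    contexts = dict(contexts or {})
    unknown = sorted(set(contexts) - set(tables))
    if unknown:
        raise ValueError(f"contexts for unknown datasets: {unknown}")

    raw: dict[str, ExposureProfile] = {}
    refined: dict[str, ExposureProfile] = {}
    refined_tables: dict[str, AnnotationTable] = {}
    errors: dict[str, str] = {}
    for name, table in tables.items():
        context = contexts.get(name, SampleContext.NONE)
        try:
            raw[name] = compute_profile(table)
            refined_table = table.refined(context)
            refined_tables[name] = refined_table
            refined[name] = compute_profile(refined_table)
        except ValueError as exc:
            errors[name] = str(exc)
    return DatasetProfiles(raw=raw, refined=refined, refined_tables=refined_tables, errors=errors)
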