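import random

import pytest

from exposource.evaluation import (
    BenchmarkPair,
    agreement_and_difference,
    harmonize_vocabulary,
    pairs_from_tables,
    per_category_metrics,
    reproducibility,
    strip_category,
)
from exposource.labels import DEFAULT_VOCABULARY, INFO, LabelSet


def P(compound, ref, pred):
    return BenchmarkPair(
        compound=compound,
        reference=LabelSet(frozenset(ref)),
        predicted=LabelSet(frozenset(pred)) if pred is not None else None,
    )


HAND_PAIRS = [
    P("a", {"MEDICAL"}, {"MEDICAL", "INDUSTRIAL"}),
    P("b", {"FOOD"}, {"FOOD"}),
    P("c", {"FOOD", "ENDOGENOUS"}, {"ENDOGENOUS"}),
    P("d", {"MEDICAL"}, {"MEDICAL"}),
]


class TestPerCategoryMetrics:
    def test_hand_counted_example(self):
        table = per_category_metrics(HAND_PAIRS)
        food = table.category("FOOD")
        assert (food.tp, food.fp, food.fn) == (1, 0, 1)
        assert food.precision == 1.0
        assert food.recall == 0.5
        assert food.f1 == pytest.approx(2 / 3)
        industrial = table.category("INDUSTRIAL")
        assert (industrial.tp, industrial.fp) == (0, 1)
        assert industrial.precision == 0.0
        assert industrial.recall is None  # no INDUSTRIAL reference anywhere

    def test_perfect_predictions_score_one_everywhere(self):
        pairs = [P(c, s, s) for c, s in
                 [("a", {"MEDICAL"}), ("b", {"FOOD", "ENDOGENOUS"}), ("c", {"PERSONAL CARE"})]]
        table = per_category_metrics(pairs)
        for m in table.per_category:
            if m.tp:
                assert m.precision == m.recall == m.f1 == 1.0
        assert table.exact_agreement == 1.0

    def test_category_in_every_reference_has_perfect_precision(self):
        rng = random.Random(0)
        pairs = []
        for i in range(50):
            ref = {"MEDICAL"} | set(rng.sample(DEFAULT_VOCABULARY[1:], rng.randint(0, 2)))
            pred = set(rng.sample(DEFAULT_VOCABULARY, rng.randint(1, 5)))
            pairs.append(P(f"c{i}", ref, pred))
        medical = per_category_metrics(pairs).category("MEDICAL")
        if medical.precision is not None:
            assert medical.precision == 1.0

    def test_undefined_metrics_are_none_not_zero(self):
        table = per_category_metrics([P("a", {"FOOD"}, {"FOOD"})])
        personal = table.category("PERSONAL CARE")
        assert personal.precision is None and personal.recall is None

    def test_out_of_vocabulary_label_names_compound(self):
        pair = P("weird", {"MEDICAL"}, {"MEDICAL"})
        with pytest.raises(ValueError, match="weird"):
            per_category_metrics([pair], vocabulary=("FOOD",))

    def test_info_predictions_excluded_by_default_but_countable(self):
        pairs = HAND_PAIRS + [P("e", {"FOOD"}, {INFO})]
        assert per_category_metrics(pairs).n_pairs == 4
        table = per_category_metrics(pairs, include_info=True)
        assert table.n_pairs == 5
        # the INFO prediction disagrees with its non-empty reference
        assert table.category("FOOD").fn == 2

    def test_conservation_of_counts(self):
        rng = random.Random(1)
        pairs = [
            P(f"c{i}",
              set(rng.sample(DEFAULT_VOCABULARY, rng.randint(1, 3))),
              set(rng.sample(DEFAULT_VOCABULARY, rng.randint(1, 3))))
            for i in range(30)
        ]
        table = per_category_metrics(pairs)
        for m in table.per_category:
            n_ref = sum(m.category in p.reference for p in pairs)
            n_pred = sum(m.category in p.predicted for p in pairs)
            assert m.tp + m.fn == n_ref
            assert m.tp + m.fp == n_pred

    def test_matches_sklearn_multilabel_metrics(self):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        import numpy as np

        rng = random.Random(2)
        pairs = [
            P(f"c{i}",
              set(rng.sample(DEFAULT_VOCABULARY, rng.randint(1, 3))),
              set(rng.sample(DEFAULT_VOCABULARY, rng.randint(1, 3))))
            for i in range(40)
        ]
        y_true = np.array([[c in p.reference for c in DEFAULT_VOCABULARY] for p in pairs])
        y_pred = np.array([[c in p.predicted for c in DEFAULT_VOCABULARY] for p in pairs])
        precision, recall, f1, _ = sklearn_metrics.precision_recall_fscore_support(
            y_true, y_pred, average=None, zero_division=np.nan
        )
        table = per_category_metrics(pairs)
        for j, m in enumerate(table.per_category):
            if m.precision is not None:
                assert m.precision == pytest.approx(precision[j])
            if m.recall is not None:
                assert m.recall == pytest.approx(recall[j])
            if m.f1 is not None:
                assert m.f1 == pytest.approx(f1[j])


class TestAgreementAndDifference:
    def test_identical_pairs(self):
        pairs = [P(f"c{i}", {"FOOD"}, {"FOOD"}) for i in range(3)]
        exact, histogram = agreement_and_difference(pairs)
        assert exact == 1.0 and histogram == {0: 1.0}

    def test_single_extra_label_differs_by_one(self):
        exact, histogram = agreement_and_difference(
            [P("a", {"MEDICAL"}, {"MEDICAL", "INDUSTRIAL"})]
        )
        assert exact == 0.0 and histogram == {1: 1.0}

    def test_constructed_difference_distribution(self):
        pairs = (
            [P(f"e{i}", {"FOOD"}, {"FOOD"}) for i in range(5)]
            + [P(f"o{i}", {"FOOD"}, {"FOOD", "MEDICAL"}) for i in range(3)]
            + [P(f"t{i}", {"FOOD"}, {"MEDICAL"}) for i in range(2)]
        )
        exact, histogram = agreement_and_difference(pairs)
        assert histogram == {0: 0.5, 1: 0.3, 2: 0.2}
        assert exact == histogram[0]
        assert sum(histogram.values()) == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_reference_and_predicted(self):
        rng = random.Random(3)
        pairs = [
            P(f"c{i}",
              set(rng.sample(DEFAULT_VOCABULARY, rng.randint(1, 3))),
              set(rng.sample(DEFAULT_VOCABULARY, rng.randint(1, 3))))
            for i in range(20)
        ]
        swapped = [P(p.compound, p.predicted.labels, p.reference.labels) for p in pairs]
        assert agreement_and_difference(pairs) == agreement_and_difference(swapped)


class TestOracleEquivalence:
    @staticmethod
    def oracle(pairs, vocabulary):
        """Brute-force per-pair enumeration of all metrics."""
        per_cat = {}
        for c in vocabulary:
            tp = sum(1 for p in pairs if c in p.reference.labels and c in p.predicted.labels)
            fp = sum(1 for p in pairs if c not in p.reference.labels and c in p.predicted.labels)
            fn = sum(1 for p in pairs if c in p.reference.labels and c not in p.predicted.labels)
            per_cat[c] = (
                tp, fp, fn,
                tp / (tp + fp) if tp + fp else None,
                tp / (tp + fn) if tp + fn else None,
            )
        n = len(pairs)
        diffs = [len(p.reference.labels ^ p.predicted.labels) for p in pairs]
        exact = sum(d == 0 for d in diffs) / n
        histogram = {k: diffs.count(k) / n for k in sorted(set(diffs))}
        return per_cat, exact, histogram

    def test_metrics_match_brute_force_on_random_benchmarks(self):
        vocabulary = DEFAULT_VOCABULARY[:3]
        rng = random.Random(12345)
        for _ in range(200):
            n = rng.randint(1, 20)
            pairs = [
                P(f"c{i}",
                  set(rng.sample(vocabulary, rng.randint(1, 3))),
                  set(rng.sample(vocabulary, rng.randint(1, 3))))
                for i in range(n)
            ]
            expected, exact, histogram = self.oracle(pairs, vocabulary)
            table = per_category_metrics(pairs, vocabulary)
            for m in table.per_category:
                tp, fp, fn, precision, recall = expected[m.category]
                assert (m.tp, m.fp, m.fn) == (tp, fp, fn)
                assert m.precision == precision
                assert m.recall == recall
            assert table.exact_agreement == exact
            assert dict(table.difference_histogram) == histogram


class TestStripCategory:
    def test_pair_dropped_when_reference_emptied(self):
        assert strip_category([P("a", {"MEDICAL"}, {"MEDICAL"})], "MEDICAL") == []

    def test_emptied_prediction_becomes_disagreement_marker(self):
        [pair] = strip_category([P("a", {"MEDICAL", "FOOD"}, {"MEDICAL"})], "MEDICAL")
        assert pair.reference.labels == {"FOOD"}
        assert pair.predicted is None
        assert pair.difference == 1

    def test_absent_category_leaves_pairs_unchanged(self):
        stripped = strip_category(HAND_PAIRS, "PERSONAL CARE")
        assert [(p.reference.labels, p.predicted.labels) for p in stripped] == \
               [(p.reference.labels, p.predicted.labels) for p in HAND_PAIRS]

    def test_agreement_recomputable_after_strip(self):
        pairs = [
            P("a", {"MEDICAL", "FOOD"}, {"MEDICAL", "FOOD"}),
            P("b", {"MEDICAL"}, {"MEDICAL"}),
            P("c", {"MEDICAL", "ENDOGENOUS"}, {"MEDICAL"}),
        ]
        stripped = strip_category(pairs, "MEDICAL")
        exact, _ = agreement_and_difference(stripped, include_info=True)
        assert exact == 0.5  # "a" agrees on FOOD; "c" predicted nothing nonmedical


class TestReproducibility:
    def test_rates_from_run_counts(self):
        runs = {
            "stable": [LabelSet.of("INDUSTRIAL")] * 100,
            "wobbly": [LabelSet.of("INDUSTRIAL")] * 88 + [LabelSet.of("MEDICAL")] * 12,
        }
        report = reproducibility(runs, "INDUSTRIAL")
        assert report.rate("stable") == 1.0
        assert report.rate("wobbly") == 0.88
        assert report.n_always() == 1

    def test_zero_occurrences(self):
        report = reproducibility({"c": [LabelSet.of("FOOD")] * 10}, "INDUSTRIAL")
        assert report.rate("c") == 0.0

    def test_unequal_run_counts_rejected(self):
        runs = {"a": [LabelSet.of("FOOD")] * 3, "b": [LabelSet.of("FOOD")] * 2}
        with pytest.raises(ValueError):
            reproducibility(runs, "FOOD")


class TestHarmonizeVocabulary:
    def test_external_term_mapped_to_canonical_category(self):
        external = LabelSet.of("COSMETIC_INGREDIENT", vocabulary=("COSMETIC_INGREDIENT",))
        mapped = harmonize_vocabulary(external, {"COSMETIC_INGREDIENT": "PERSONAL CARE"})
        assert mapped.labels == {"PERSONAL CARE"}

    def test_identity_mapping_preserves_labels(self):
        labels = LabelSet.of("FOOD", "MEDICAL")
        assert harmonize_vocabulary(labels, {c: c for c in DEFAULT_VOCABULARY}).labels == \
            labels.labels

    def test_two_terms_collapsing_deduplicate(self):
        external = LabelSet.of("SOLVENT", "PLASTICIZER", vocabulary=("SOLVENT", "PLASTICIZER"))
        mapped = harmonize_vocabulary(
            external, {"SOLVENT": "INDUSTRIAL", "PLASTICIZER": "INDUSTRIAL"}
        )
        assert mapped.labels == {"INDUSTRIAL"}

    def test_unmapped_term_is_an_error(self):
        with pytest.raises(ValueError, match="FOOD"):
            harmonize_vocabulary(LabelSet.of("FOOD"), {"MEDICAL": "MEDICAL"})


class TestTableIO:
    def test_pairs_join_on_compound(self):
        import pandas as pd

        ref = pd.DataFrame({"compound": ["a", "b"], "labels": ["MEDICAL", "FOOD;MEDICAL"]})
        pred = pd.DataFrame({"compound": ["b", "a"], "labels": ["FOOD", "MEDICAL"]})
        pairs = {p.compound: p for p in pairs_from_tables(ref, pred)}
        assert pairs["b"].reference.labels == {"FOOD", "MEDICAL"}
        assert pairs["b"].predicted.labels == {"FOOD"}

    def test_missing_prediction_key_is_an_error(self):
        import pandas as pd

        ref = pd.DataFrame({"compound": ["a", "zz"], "labels": ["MEDICAL", "FOOD"]})
        pred = pd.DataFrame({"compound": ["a"], "labels": ["MEDICAL"]})
        with pytest.raises(ValueError, match="zz"):
            pairs_from_tables(ref, pred)
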