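import pytest

from phenoprompt.corpus import AnnotationSet, Document, EntityMention
from phenoprompt.evaluation import (
    ERROR_CATEGORIES,
    ErrorRecord,
    Metrics,
    assign_matches,
    classify_errors,
    compute_metrics,
    error_table,
    evaluate_corpus,
    is_exact_match,
    is_relaxed_match,
)


def mention(start, end, etype, doc):
    return EntityMention.from_document(doc, [(start, end)], etype)


@pytest.fixture
def doc():
    return Document(doc_id="d", text="Keratomalacia is a cause of corneal scarring.")


class TestExactMatch:
    def test_identity(self, doc):
        g = mention(28, 44, "sign", doc)
        p = mention(28, 44, "sign", doc)
        assert is_exact_match(g, p, doc)

    def test_type_mismatch(self, doc):
        g = mention(28, 44, "sign", doc)
        p = mention(28, 44, "symptom", doc)
        assert not is_exact_match(g, p, doc)

    def test_boundary_mismatch(self, doc):
        g = mention(28, 44, "sign", doc)
        p = mention(36, 44, "sign", doc)  # "scarring" only
        assert not is_exact_match(g, p, doc)

    def test_stop_word_boundary_difference_matches(self):
        text = "marked distention of the kidney was noted."
        d = Document(doc_id="k", text=text)
        g = mention(7, 31, "sign", d)  # "distention of the kidney"
        p = mention(7, 17, "sign", d)  # "distention"
        assert not is_exact_match(g, p, d)
        # differing only by trailing stop words: "distention of the" vs "distention"
        p2 = mention(7, 24, "sign", d)
        assert d.text[7:24] == "distention of the"
        assert is_exact_match(g, p2, d) is False  # content tokens differ (kidney)
        # gold "of the kidney" vs pred "kidney": leading stop words trimmed
        g2 = mention(18, 31, "sign", d)
        p3 = mention(25, 31, "sign", d)
        assert d.text[18:31] == "of the kidney"
        assert d.text[25:31] == "kidney"
        assert is_exact_match(g2, p3, d)

    def test_ungrounded_prediction_never_matches(self, doc):
        g = mention(28, 44, "sign", doc)
        p = EntityMention.ungrounded("corneal scarring", "sign")
        assert not is_exact_match(g, p, doc)
        assert not is_relaxed_match(g, p)

    def test_discontinuous_requires_identical_fragments(self):
        d = Document(doc_id="d2", text="corneal and retinal scarring here")
        g = EntityMention.from_document(d, [(0, 7), (20, 28)], "sign")
        p_same = EntityMention.from_document(d, [(0, 7), (20, 28)], "sign")
        p_diff = EntityMention.from_document(d, [(0, 7)], "sign")
        assert is_exact_match(g, p_same, d)
        assert not is_exact_match(g, p_diff, d)
        assert is_relaxed_match(g, p_diff)


class TestRelaxedMatch:
    def test_overlap_same_type(self, doc):
        g = mention(28, 44, "sign", doc)
        p = mention(36, 44, "sign", doc)
        assert is_relaxed_match(g, p)

    def test_disjoint_same_type(self, doc):
        assert not is_relaxed_match(mention(0, 13, "sign", doc), mention(28, 44, "sign", doc))

    def test_overlap_different_type(self, doc):
        assert not is_relaxed_match(mention(28, 44, "sign", doc), mention(36, 44, "symptom", doc))

    def test_exact_implies_relaxed(self, doc):
        g = mention(28, 44, "sign", doc)
        p = mention(28, 44, "sign", doc)
        assert is_exact_match(g, p, doc) and is_relaxed_match(g, p)


class TestAssignMatches:
    def test_identical_sets_fully_paired(self, doc, ):
        gold = AnnotationSet("d", "gold", [mention(0, 13, "rare_disease", doc), mention(28, 44, "sign", doc)])
        pred = AnnotationSet("d", "predicted", list(gold.mentions))
        for mode in ("exact", "relaxed"):
            rep = assign_matches(doc, gold, pred, mode)
            assert rep.n_correct == 2
            assert rep.unmatched_gold == rep.unmatched_pred == []

    def test_one_gold_two_overlapping_predictions(self, doc):
        gold = AnnotationSet("d", "gold", [mention(28, 44, "sign", doc)])
        pred = AnnotationSet(
            "d", "predicted", [mention(28, 44, "sign", doc), mention(36, 44, "sign", doc)]
        )
        rep = assign_matches(doc, gold, pred, "relaxed")
        assert rep.n_correct == 1
        assert len(rep.unmatched_pred) == 1

    def test_exact_priority_in_relaxed_mode(self, doc):
        gold = AnnotationSet("d", "gold", [mention(28, 44, "sign", doc)])
        pred = AnnotationSet(
            "d", "predicted", [mention(36, 44, "sign", doc), mention(28, 44, "sign", doc)]
        )
        rep = assign_matches(doc, gold, pred, "relaxed")
        assert rep.pairs == [(0, 1, True)]  # the exact prediction wins

    def test_mismatched_doc_ids(self, doc):
        gold = AnnotationSet("d", "gold", [])
        pred = AnnotationSet("other", "predicted", [])
        with pytest.raises(ValueError, match="mismatch"):
            assign_matches(doc, gold, pred, "exact")

    def test_augmentation_beats_pure_greedy(self):
        # g0 exactly matches p0; g1 overlaps only p0; g0 also overlaps p1.
        # Maximum relaxed matching pairs both golds, re-pairing g0 to p1.
        text = "alpha beta gamma delta"
        d = Document(doc_id="x", text=text)
        g0 = mention(0, 10, "sign", d)
        g1 = mention(5, 16, "sign", d)
        p0 = mention(0, 10, "sign", d)
        p1 = mention(11, 22, "sign", d)
        gold = AnnotationSet("x", "gold", [g0, g1])
        # p0 overlaps both golds; p1 overlaps only g1
        pred = AnnotationSet("x", "predicted", [p0, p1])
        rep = assign_matches(d, gold, pred, "relaxed")
        assert rep.n_correct == 2


class TestComputeMetrics:
    @pytest.mark.parametrize(
        "precision,recall,f1",
        [
            (0.843, 0.694, 0.761),  # printed per-type row
            (0.5, 0.5, 0.5),
            (0.203, 0.369, 0.262),
        ],
    )
    def test_harmonic_mean(self, precision, recall, f1):
        # reconstruct integer counts approximating the rates, then check the formula
        m_hat, m = 1000, 1000
        metrics = Metrics.from_counts(0, m, m_hat)
        # direct formula check at the printed precision/recall
        computed = 2 * precision * recall / (precision + recall)
        from phenoprompt.corpus import round_half_up

        assert round_half_up(computed, 3) == f1
        assert metrics.f1 == 0.0

    def test_zero_denominators(self):
        m = Metrics.from_counts(0, 0, 0)
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        m2 = Metrics.from_counts(0, 5, 0)
        assert (m2.precision, m2.recall, m2.f1) == (0.0, 0.0, 0.0)

    def test_micro_aggregation(self, doc):
        gold = AnnotationSet("d", "gold", [mention(0, 13, "rare_disease", doc)])
        pred_hit = AnnotationSet("d", "predicted", [mention(0, 13, "rare_disease", doc)])
        doc2 = Document(doc_id="e", text=doc.text)
        gold2 = AnnotationSet("e", "gold", [mention(0, 13, "rare_disease", doc2)])
        pred_miss = AnnotationSet("e", "predicted", [])
        reports = [
            assign_matches(doc, gold, pred_hit, "exact"),
            assign_matches(doc2, gold2, pred_miss, "exact"),
        ]
        metrics = compute_metrics(reports)
        assert metrics.m == 2 and metrics.m_hat == 1 and metrics.n_correct == 1
        assert metrics.precision == 1.0 and metrics.recall == 0.5

    def test_duplicate_documents_rejected(self, doc):
        gold = AnnotationSet("d", "gold", [])
        pred = AnnotationSet("d", "predicted", [])
        rep = assign_matches(doc, gold, pred, "exact")
        with pytest.raises(ValueError, match="duplicate"):
            compute_metrics([rep, rep])

    def test_evaluate_corpus_per_type_and_overall(self, doc):
        gold = {"d": AnnotationSet("d", "gold", [mention(0, 13, "rare_disease", doc), mention(28, 44, "sign", doc)])}
        pred = {"d": AnnotationSet("d", "predicted", [mention(0, 13, "rare_disease", doc)])}
        out = evaluate_corpus({"d": doc}, gold, pred, "exact")
        assert out["rare_disease"].f1 == 1.0
        assert out["sign"].recall == 0.0
        assert out["overall"].m == 2 and out["overall"].m_hat == 1

    def test_missing_prediction_docs_count_as_empty(self, doc):
        gold = {"d": AnnotationSet("d", "gold", [mention(0, 13, "rare_disease", doc)])}
        out = evaluate_corpus({"d": doc}, gold, {}, "relaxed")
        assert out["overall"].recall == 0.0 and out["overall"].m == 1


class TestClassifyErrors:
    def test_spurious(self, doc):
        gold = AnnotationSet("d", "gold", [])
        pred = AnnotationSet("d", "predicted", [mention(28, 44, "sign", doc)])
        records = classify_errors(doc, gold, pred)
        assert [r.category for r in records] == ["spurious"]
        assert records[0].entity_type == "sign"
        assert records[0].gold_index is None

    def test_missed(self, doc):
        gold = AnnotationSet("d", "gold", [mention(28, 44, "sign", doc)])
        pred = AnnotationSet("d", "predicted", [])
        records = classify_errors(doc, gold, pred)
        assert [r.category for r in records] == ["missed"]
        assert records[0].pred_index is None

    def test_type_only(self, doc):
        gold = AnnotationSet("d", "gold", [mention(0, 13, "rare_disease", doc)])
        pred = AnnotationSet("d", "predicted", [mention(0, 13, "disease", doc)])
        records = classify_errors(doc, gold, pred)
        assert [r.category for r in records] == ["type_only"]
        # attributed to the gold mention's type
        assert records[0].entity_type == "rare_disease"

    def test_boundary_only(self, doc):
        gold = AnnotationSet("d", "gold", [mention(28, 44, "sign", doc)])
        pred = AnnotationSet("d", "predicted", [mention(36, 44, "sign", doc)])
        records = classify_errors(doc, gold, pred)
        assert [r.category for r in records] == ["boundary_only"]

    def test_boundary_and_type(self, doc):
        gold = AnnotationSet("d", "gold", [mention(28, 44, "sign", doc)])
        pred = AnnotationSet("d", "predicted", [mention(36, 44, "symptom", doc)])
        records = classify_errors(doc, gold, pred)
        assert [r.category for r in records] == ["boundary_and_type"]
        assert records[0].entity_type == "sign"  # gold-side attribution

    def test_exact_match_no_record(self, doc, fig_gold):
        gold = AnnotationSet("d", "gold", [mention(0, 13, "rare_disease", doc)])
        pred = AnnotationSet("d", "predicted", [mention(0, 13, "rare_disease", doc)])
        assert classify_errors(doc, gold, pred) == []

    def test_partition_identities(self, doc):
        gold = AnnotationSet(
            "d",
            "gold",
            [mention(0, 13, "rare_disease", doc), mention(28, 44, "sign", doc)],
        )
        pred = AnnotationSet(
            "d",
            "predicted",
            [
                mention(0, 13, "disease", doc),  # type_only
                mention(36, 44, "sign", doc),  # boundary_only
                mention(17, 22, "symptom", doc),  # spurious ("cause")
            ],
        )
        records = classify_errors(doc, gold, pred)
        by_cat = {c: sum(1 for r in records if r.category == c) for c in ERROR_CATEGORIES}
        n_exact = 0
        m, m_hat = len(gold), len(pred)
        assert n_exact + by_cat["boundary_only"] + by_cat["type_only"] + by_cat["boundary_and_type"] + by_cat["spurious"] == m_hat
        assert n_exact + by_cat["boundary_only"] + by_cat["type_only"] + by_cat["boundary_and_type"] + by_cat["missed"] == m


class TestErrorTable:
    def test_printed_rare_disease_row_total(self):
        records = (
            [ErrorRecord("boundary_only", "rare_disease", 0, 0)] * 16
            + [ErrorRecord("type_only", "rare_disease", 0, 0)] * 48
            + [ErrorRecord("boundary_and_type", "rare_disease", 0, 0)] * 17
            + [ErrorRecord("spurious", "rare_disease", None, 0)] * 4
            + [ErrorRecord("missed", "rare_disease", 0, None)] * 72
        )
        table = error_table(records)
        assert table.total("rare_disease") == 157
        assert table.percentage("rare_disease", "boundary_only") == 10
        assert table.percentage("rare_disease", "type_only") == 31
        assert table.percentage("rare_disease", "boundary_and_type") == 11
        assert table.percentage("rare_disease", "spurious") == 3

    def test_printed_disease_spurious_percentage(self):
        records = (
            [ErrorRecord("boundary_only", "disease", 0, 0)] * 11
            + [ErrorRecord("type_only", "disease", 0, 0)] * 7
            + [ErrorRecord("boundary_and_type", "disease", 0, 0)] * 9
            + [ErrorRecord("spurious", "disease", None, 0)] * 147
            + [ErrorRecord("missed", "disease", 0, None)] * 116
        )
        table = error_table(records)
        assert table.total("disease") == 290
        assert table.percentage("disease", "spurious") == 51

    def test_empty_table(self):
        table = error_table([])
        for etype in ("rare_disease", "disease", "symptom", "sign"):
            assert table.total(etype) == 0
            assert all(table.percentage(etype, c) == 0 for c in ERROR_CATEGORIES)

    def test_percentages_sum_to_100_within_slack(self):
        records = (
            [ErrorRecord("boundary_only", "sign", 0, 0)] * 64
            + [ErrorRecord("type_only", "sign", 0, 0)] * 8
            + [ErrorRecord("boundary_and_type", "sign", 0, 0)] * 5
            + [ErrorRecord("spurious", "sign", None, 0)] * 146
            + [ErrorRecord("missed", "sign", 0, None)] * 148
        )
        table = error_table(records)
        total_pct = sum(table.percentage("sign", c) for c in ERROR_CATEGORIES)
        assert abs(total_pct - 100) <= 2

    def test_csv_shape(self):
        table = error_table([ErrorRecord("missed", "sign", 0, None)])
        csv_text = table.to_csv()
        lines = csv_text.strip().splitlines()
        assert len(lines) == 5  # header + four entity rows
        assert lines[0].startswith("entity,boundary_only")


class TestErrorRecordInvariants:
    def test_spurious_no_gold_index(self):
        with pytest.raises(ValueError):
            ErrorRecord("spurious", "sign", gold_index=1, pred_index=0)

    def test_missed_no_pred_index(self):
        with pytest.raises(ValueError):
            ErrorRecord("missed", "sign", gold_index=0, pred_index=1)

    def test_invalid_category(self):
        with pytest.raises(ValueError):
            ErrorRecord("bogus", "sign")
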