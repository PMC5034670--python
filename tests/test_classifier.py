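"""Prioritization rules, full-pipeline classification and the baseline."""

import pytest

from gbdmap.classifier import (
    ALL_VARIANTS,
    ClassifierConfig,
    TrialRecord,
    baseline_classify,
    classify_batch,
    classify_trial,
    packaged_name_index,
    prioritize,
)
from gbdmap.projection import Pathway
from gbdmap.taxonomy import parse_icd10


def _pw(field, cui, icd, cat, enrich=False):
    return Pathway("T", field, cui, None if icd is None else parse_icd10(icd), cat, enrich)


class TestPrioritize:
    def test_empty_input(self):
        assert prioritize([]) == set()

    def test_consistent_pathways_agree(self):
        pws = [
            _pw("condition", "C1", "M16", "musculoskeletal"),
            _pw("public_title", "C1", "M16", "musculoskeletal"),
        ]
        assert prioritize(pws, field_priority=True) == {"musculoskeletal"}

    def test_field_priority_restricts_to_condition(self):
        pws = [
            _pw("condition", "C1", "M16", "A"),
            _pw("public_title", "C2", "J45", "B"),
        ]
        assert prioritize(pws, field_priority=True) == {"A"}
        assert prioritize(pws, field_priority=False) == {"A", "B"}

    def test_field_priority_falls_back_to_titles(self):
        pws = [_pw("scientific_title", "C2", "J45", "B")]
        assert prioritize(pws, field_priority=True) == {"B"}

    def test_multiplicity_rule_drops_isolated_categories(self):
        pws = [
            _pw("condition", "C1", "M16", "A"),
            _pw("condition", "C1", "M16.9", "A"),
            _pw("condition", "C2", "M17", "A"),
            _pw("condition", "C3", "J45", "B"),
        ]
        assert prioritize(pws) == {"A"}

    def test_all_isolated_categories_kept(self):
        pws = [
            _pw("condition", "C1", "M16", "A"),
            _pw("condition", "C3", "J45", "B"),
        ]
        assert prioritize(pws) == {"A", "B"}

    def test_support_unit_is_distinct_cui_code_pair(self):
        # same (cui, code) appearing in two fields counts once
        pws = [
            _pw("condition", "C1", "M16", "A"),
            _pw("public_title", "C1", "M16", "A"),
            _pw("condition", "C2", "J45", "B"),
            _pw("condition", "C2", "J45.9", "B"),
        ]
        assert prioritize(pws, field_priority=False) == {"B"}

    def test_enrichment_route_counts_as_one_support(self):
        pws = [
            _pw("condition", "C1", None, "A", enrich=True),
            _pw("condition", "C2", "J45", "B"),
            _pw("condition", "C2", "J45.9", "B"),
        ]
        assert prioritize(pws) == {"B"}

    def test_final_set_subset_of_condition_candidates(self):
        pws = [
            _pw("condition", "C1", "M16", "A"),
            _pw("condition", "C2", "J45", "B"),
            _pw("public_title", "C3", "K70", "C"),
        ]
        condition_cats = {p.category_id for p in pws if p.field_name == "condition"}
        assert prioritize(pws, field_priority=True) <= condition_cats


class TestClassifyTrial:
    def test_worked_example_all_variants(self, oa_lexicon, gbd28):
        """The knee/hip osteoarthritis record maps to musculoskeletal under
        every combination of the three classifier switches."""
        trial = TrialRecord(
            "NCT001",
            condition="Knee Osteoarthritis; Hip Osteoarthritis",
            public_title="Knee and Hip Osteoarthritis Study",
            scientific_title="A trial for patients with knee osteoarthritis or hip osteoarthritis",
        )
        assert len(ALL_VARIANTS) == 8
        for config in ALL_VARIANTS:
            result = classify_trial(trial, oa_lexicon, gbd28, config=config)
            assert result.categories == {"musculoskeletal"}, config
            assert not result.no_gbd

    def test_all_fields_empty_is_no_gbd(self, oa_lexicon, gbd28):
        result = classify_trial(TrialRecord("NCT002"), oa_lexicon, gbd28)
        assert result.no_gbd and result.categories == frozenset()

    def test_irrelevant_condition_is_no_gbd(self, oa_lexicon, gbd28):
        result = classify_trial(
            TrialRecord("NCT003", condition="pain management"), oa_lexicon, gbd28
        )
        assert result.no_gbd

    def test_titles_rescue_empty_condition(self, oa_lexicon, gbd28):
        trial = TrialRecord("NCT004", public_title="Study of hip osteoarthritis")
        result = classify_trial(
            trial, oa_lexicon, gbd28, config=ClassifierConfig(field_priority=True)
        )
        assert result.categories == {"musculoskeletal"}

    def test_deterministic(self, oa_lexicon, gbd28):
        trial = TrialRecord("NCT005", condition="osteoarthritis of hip and arthritis")
        for config in ALL_VARIANTS:
            a = classify_trial(trial, oa_lexicon, gbd28, config=config)
            b = classify_trial(trial, oa_lexicon, gbd28, config=config)
            assert a == b

    def test_external_annotations_replace_matcher(self, oa_lexicon, gbd28):
        from gbdmap.annotation import Annotation

        trial = TrialRecord("NCT006", condition="coxarthrosis")  # not a lexicon term
        anns = {"condition": [Annotation("condition", 0, 12, "coxarthrosis", "C0029410")]}
        result = classify_trial(trial, oa_lexicon, gbd28, annotations=anns)
        assert result.categories == {"musculoskeletal"}

    def test_external_annotation_span_mismatch_rejected(self, oa_lexicon, gbd28):
        from gbdmap.annotation import Annotation, AnnotationError

        trial = TrialRecord("NCT007", condition="asthma")
        anns = {"condition": [Annotation("condition", 0, 12, "coxarthrosis", "C0029410")]}
        with pytest.raises(AnnotationError):
            classify_trial(trial, oa_lexicon, gbd28, annotations=anns)


class TestClassifyBatch:
    def test_order_preserved(self, oa_lexicon, gbd28):
        trials = [TrialRecord(f"T{i}", condition="arthritis") for i in range(10)]
        results = classify_batch(trials, oa_lexicon, gbd28)
        assert [r.trial_id for r in results] == [t.trial_id for t in trials]

    def test_failing_record_logged_and_skipped(self, oa_lexicon, gbd28, caplog):
        from gbdmap.annotation import Annotation

        trials = [TrialRecord("OK1", condition="arthritis"), TrialRecord("BAD"), TrialRecord("OK2")]
        bad_anns = {"BAD": {"condition": [Annotation("condition", 0, 5, "wrong", "C1")]}}
        with caplog.at_level("ERROR"):
            results = classify_batch(trials, oa_lexicon, gbd28, annotations=bad_anns)
        assert [r.trial_id for r in results] == ["OK1", "OK2"]
        assert any("BAD" in rec.message for rec in caplog.records)

    def test_empty_batch(self, oa_lexicon, gbd28):
        assert classify_batch([], oa_lexicon, gbd28) == []


class TestBaseline:
    def test_verbatim_containment(self):
        index = packaged_name_index()
        trial = TrialRecord("T1", condition="Malaria prophylaxis trial")
        assert baseline_classify(trial, index, fields="condition") == {"malaria"}

    def test_no_defining_name_no_category(self):
        index = packaged_name_index()
        trial = TrialRecord("T1", condition="Knee problems")
        assert baseline_classify(trial, index, fields="condition") == set()

    def test_field_selection(self):
        index = packaged_name_index()
        trial = TrialRecord("T1", scientific_title="Asthma control study")
        assert baseline_classify(trial, index, fields="condition") == set()
        assert baseline_classify(trial, index, fields="scientific") == {"chronic_respiratory"}
        assert baseline_classify(trial, index, fields="all") == {"chronic_respiratory"}

    def test_word_boundary_required(self):
        index = {"gout_cat": ["Gout"]}
        assert baseline_classify(TrialRecord("T1", condition="Gouty arthropathy"), index) == set()
        assert baseline_classify(TrialRecord("T1", condition="Chronic gout."), index) == {"gout_cat"}

    def test_case_insensitive(self):
        index = packaged_name_index()
        trial = TrialRecord("T1", condition="newly diagnosed TUBERCULOSIS")
        assert baseline_classify(trial, index) == {"tuberculosis"}

    def test_unknown_selector_rejected(self):
        with pytest.raises(ValueError):
            baseline_classify(TrialRecord("T1"), {}, fields="summary")
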