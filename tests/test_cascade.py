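"""Rules-then-SVM cascade, ICD positivity, grouping, and tallies."""

import datetime as dt

import pytest

import opionlp as o
from opionlp.cascade import (
    GROUP_ALL_ICD,
    GROUP_NLP_ONLY,
    GROUP_NONE,
    GROUP_NLP_ICD,
)
from opionlp.lexicon import snippet_from_text


def _snip(text, key, pid="p1", nid="n1"):
    return snippet_from_text(text, key, note_id=nid, patient_id=pid)


class TestClassifySnippet:
    def test_rule_decision_taken_when_available(self, library, trained):
        c = o.classify_snippet(
            _snip("former opioid dependence", "opioid dependence"),
            library,
            trained.model,
        )
        assert (c.label, c.method, c.tier) == ("negative", "rule", "canceling")

    def test_pattern_free_snippet_falls_through_to_svm(self, library, trained):
        c = o.classify_snippet(
            _snip("ongoing misuse of morphine with escalating doses and cravings reported", "morphine"),
            library,
            trained.model,
        )
        assert c.method == "svm" and c.label == "positive"

    def test_batch_coverage_is_total(self, library, trained, separable_corpus):
        snippets, _, _ = separable_corpus
        out = o.classify_snippets(snippets[:200], library, trained.model)
        assert len(out) == 200
        assert all(c.label in ("positive", "negative") for c in out)

    def test_batch_agrees_with_single_classification(
        self, library, trained, separable_corpus
    ):
        snippets, _, _ = separable_corpus
        batch = o.classify_snippets(snippets[:50], library, trained.model)
        single = [o.classify_snippet(s, library, trained.model) for s in snippets[:50]]
        assert [(c.label, c.method) for c in batch] == [
            (c.label, c.method) for c in single
        ]


class TestIcdPositive:
    @pytest.mark.parametrize(
        "codes,expected",
        [
            (["F11.20"], True),
            (["304.00"], True),
            (["f11.90"], True),  # case-insensitive
            (["F10.20", "305.1"], False),
            (["304.01"], False),  # exact match for ICD-9 codes
            ([], False),
        ],
    )
    def test_qualifying_codes(self, codes, expected):
        assert o.is_icd_positive(codes) is expected


def _cohort():
    patients = [
        o.PatientRecord("a", icd_codes=[("304.00", dt.date(2015, 1, 1))]),
        o.PatientRecord("b"),
        o.PatientRecord("c"),
    ]
    pos = o.ClassifiedSnippet(_snip("opioid abuse", "opioid", pid="a"), "positive", "rule", "general_positive")
    pos_b = o.ClassifiedSnippet(_snip("opioid abuse", "opioid", pid="b", nid="n2"), "positive", "rule", "general_positive")
    neg_c = o.ClassifiedSnippet(_snip("patient requested no lortab", "lortab", pid="c"), "negative", "svm")
    return patients, [pos, pos_b, neg_c]


class TestAssignGroups:
    def test_three_way_partition(self):
        patients, classified = _cohort()
        groups = {a.patient_id: a.group for a in o.assign_groups(patients, classified)}
        assert groups == {"a": GROUP_ALL_ICD, "b": GROUP_NLP_ONLY, "c": GROUP_NONE}

    def test_coded_patient_with_positive_snippets_is_in_overlap(self):
        patients, classified = _cohort()
        by_id = {a.patient_id: a for a in o.assign_groups(patients, classified)}
        assert by_id["a"].in_overlap
        assert not by_id["b"].in_overlap

    def test_sizes_partition_cohort_and_overlap_identity(self):
        patients, classified = _cohort()
        assignments = o.assign_groups(patients, classified)
        sizes = o.group_sizes(assignments)
        assert (
            sizes[GROUP_ALL_ICD] + sizes[GROUP_NLP_ONLY] + sizes[GROUP_NONE]
            == len(patients)
        )
        assert sizes["overlap"] == sizes["nlp_positive_total"] - sizes[GROUP_NLP_ONLY]

    def test_orphan_snippet_errors_with_patient_ids(self):
        patients, classified = _cohort()
        with pytest.raises(ValueError, match="unknown patients.*zzz"):
            o.assign_groups(patients[:1], classified + [
                o.ClassifiedSnippet(_snip("opioid abuse", "opioid", pid="zzz"), "positive", "rule", "general_positive")
            ])


class TestIndexDates:
    def test_earliest_documentation_wins_and_ties_go_to_icd(self):
        d_icd = dt.date(2015, 6, 1)
        patients = [
            o.PatientRecord("a", icd_codes=[("304.00", d_icd)]),
            o.PatientRecord("b", icd_codes=[("I10", dt.date(2014, 1, 1))]),
        ]
        classified = [
            o.ClassifiedSnippet(_snip("opioid abuse", "opioid", pid="a", nid="na"), "positive", "rule", "general_positive"),
            o.ClassifiedSnippet(_snip("opioid abuse", "opioid", pid="b", nid="nb"), "positive", "rule", "general_positive"),
        ]
        note_dates = {"na": d_icd, "nb": dt.date(2016, 2, 2)}
        o.compute_index_dates(patients, classified, note_dates)
        assert patients[0].index_date == d_icd  # same-day tie -> ICD date
        # non-qualifying code never sets the index date
        assert patients[1].index_date == dt.date(2016, 2, 2)

    def test_no_documentation_leaves_index_empty(self):
        p = o.PatientRecord("x")
        o.compute_index_dates([p], [], {})
        assert p.index_date is None


class TestTally:
    def test_patient_counted_in_both_phrase_columns(self, lexicon):
        patients = [o.PatientRecord("a")]
        classified = [
            o.ClassifiedSnippet(_snip("opioid abuse oxycodone noted", "oxycodone", pid="a"), "positive", "rule", "general_positive"),
            o.ClassifiedSnippet(_snip("withdrawal noted again today ongoing", "withdrawal", pid="a"), "positive", "svm"),
        ]
        assignments = o.assign_groups(patients, classified)
        table = o.tally_positive_patterns(
            classified, lexicon, assignments, groups=(GROUP_NLP_ONLY,)
        ).iloc[0]
        assert table["patients_drug_name_positive"] == 1
        assert table["patients_other_phrase_positive"] == 1
        assert table["mean_positive_snippets"] == 2.0

    def test_no_positive_snippets_gives_zero_row(self, lexicon):
        patients = [o.PatientRecord("a")]
        classified = [
            o.ClassifiedSnippet(_snip("patient requested no lortab", "lortab", pid="a"), "negative", "svm"),
        ]
        assignments = o.assign_groups(patients, classified)
        table = o.tally_positive_patterns(
            classified, lexicon, assignments, groups=(GROUP_NLP_ONLY, GROUP_NLP_ICD)
        )
        assert (table["patients_drug_name_positive"] == 0).all()
        assert (table["mean_positive_snippets"] == 0).all()

    def test_synthetic_corpus_tally_matches_generator_truth(
        self, lexicon, library, trained, separable_corpus
    ):
        snippets, labelled, gold = separable_corpus
        classified = [
            o.ClassifiedSnippet(s, lab, "rule", "general_positive")
            for s, lab in labelled
        ]
        patients = [o.PatientRecord(pid) for pid in {s.patient_id for s in snippets}]
        assignments = o.assign_groups(patients, classified)
        table = o.tally_positive_patterns(
            classified, lexicon, assignments, groups=(GROUP_NLP_ONLY,)
        ).iloc[0]
        pos = gold[gold.label == "positive"]
        drug = set(lexicon.drug_names())
        expect_drug = pos[pos.key_phrase.isin(drug)].patient_id.nunique()
        expect_other = pos[~pos.key_phrase.isin(drug)].patient_id.nunique()
        assert table["patients_drug_name_positive"] == expect_drug
        assert table["patients_other_phrase_positive"] == expect_other
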