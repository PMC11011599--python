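"""Lexicon loading and fixed-window snippet extraction."""

import pytest
from hypothesis import given, settings, strategies as st

import opionlp as o
from opionlp.lexicon import WINDOW, _norm_token


class TestLoadLexicon:
    def test_default_lexicon_has_36_phrases(self, lexicon):
        assert len(lexicon) == 36

    def test_categories_partition_into_drug_names_and_other(self, lexicon):
        drugs = lexicon.drug_names()
        assert "oxycodone" in drugs and "methadone" in drugs
        assert lexicon.category("withdrawal") == "other"
        assert lexicon.category("opioid dependence") == "other"
        assert len(drugs) + sum(
            1 for p in lexicon.phrases if lexicon.category(p) == "other"
        ) == 36

    def test_phrases_survive_ml_preprocessing_unchanged(self, lexicon):
        # the SVM must see the key phrase intact after token cleanup
        for phrase in lexicon.phrases:
            assert o.preprocess(phrase) == phrase.split()

    def test_two_token_phrase_loaded_from_file(self, tmp_path):
        f = tmp_path / "lex.txt"
        f.write_text("opioid dependence\nfentanyl\tdrug_name\n")
        lex = o.load_lexicon(f)
        assert "opioid dependence" in lex.phrases
        assert lex.category("fentanyl") == "drug_name"

    def test_duplicate_phrase_rejected(self, tmp_path):
        f = tmp_path / "lex.txt"
        f.write_text("fentanyl\nmorphine\nfentanyl\n")
        with pytest.raises(ValueError, match="duplicate"):
            o.load_lexicon(f)

    def test_empty_file_rejected(self, tmp_path):
        f = tmp_path / "lex.txt"
        f.write_text("\n# only a comment\n")
        with pytest.raises(ValueError, match="no phrases"):
            o.load_lexicon(f)

    def test_malformed_category_names_the_line(self, tmp_path):
        f = tmp_path / "lex.txt"
        f.write_text("fentanyl\tdrug_name\nmorphine\topioid\n")
        with pytest.raises(ValueError, match=r":2.*malformed category"):
            o.load_lexicon(f)


class TestExtractSnippets:
    def test_window_geometry_mid_note(self, lexicon):
        words = ["w%d" % i for i in range(100)] + ["oxycodone"] + [
            "v%d" % i for i in range(100)
        ]
        snips = o.extract_snippets(" ".join(words), lexicon)
        assert len(snips) == 1
        s = snips[0]
        assert len(s.tokens_before) == WINDOW == len(s.tokens_after)
        assert s.key_phrase_token_index == WINDOW

    def test_boundary_truncation_never_pads(self, lexicon):
        snips = o.extract_snippets("pt requested methadone", lexicon)
        assert len(snips) == 1
        s = snips[0]
        assert s.tokens_before == ("pt", "requested")
        assert s.key_phrase_token_index == 2
        assert s.tokens_after == ()

    def test_longest_phrase_wins_at_shared_position(self, lexicon):
        # "opioid dependence": the 2-word phrase fires at the start position,
        # "opioid" is suppressed there, but "dependence" starts one later
        snips = o.extract_snippets("hx of opioid dependence noted", lexicon)
        found = {(s.key_phrase, s.key_phrase_token_index) for s in snips}
        assert found == {("opioid dependence", 2), ("dependence", 3)}

    def test_single_word_matched_elsewhere_still_fires(self, lexicon):
        snips = o.extract_snippets("opioid dependence and opioid level", lexicon)
        phrases = sorted(s.key_phrase for s in snips)
        assert phrases == ["dependence", "opioid", "opioid dependence"]

    def test_case_and_edge_punctuation_ignored(self, lexicon):
        snips = o.extract_snippets("started OxyCodone, yesterday", lexicon)
        assert [s.key_phrase for s in snips] == ["oxycodone"]
        assert snips[0].matched_tokens == ("OxyCodone,",)

    def test_empty_text_yields_empty_list(self, lexicon):
        assert o.extract_snippets("", lexicon) == []

    def test_rejoined_tokens_reproduce_snippet_text(self, lexicon):
        text = "a b c morphine d e f oxycodone g"
        for s in o.extract_snippets(text, lexicon):
            assert s.text == " ".join(
                s.tokens_before + s.matched_tokens + s.tokens_after
            )
            assert s.text in text

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.lists(
            st.sampled_from(
                ["pt", "pain", "oxycodone", "opioid", "dependence", "the", "of"]
            ),
            max_size=30,
        )
    )
    def test_matches_brute_force_position_scan(self, lexicon, tokens):
        """Snippet count equals the brute-force count of longest-match
        positions on short notes."""
        text = " ".join(tokens)
        phrase_toks = {tuple(p.split()) for p in lexicon.phrases}
        norm = [_norm_token(t) for t in tokens]
        expected = []
        for i in range(len(norm)):
            hits = [
                k for k in (2, 1)
                if tuple(norm[i : i + k]) in phrase_toks and i + k <= len(norm)
            ]
            if hits:
                k = max(hits)
                expected.append((i, " ".join(norm[i : i + k])))
        got = o.extract_snippets(text, lexicon)
        assert [(len(s.tokens_before), s.key_phrase) for s in got] == [
            (min(i, WINDOW), p) for i, p in expected
        ]
        # idempotent / deterministic
        assert [s.text for s in o.extract_snippets(text, lexicon)] == [
            s.text for s in got
        ]


class TestCountOccurrences:
    def test_counts_sum_to_snippet_total(self, lexicon):
        snips = o.extract_snippets(
            "morphine then morphine then fentanyl", lexicon, patient_id="p1"
        )
        table = o.count_key_phrase_occurrences(snips)
        assert table["n_snippets"].sum() == len(snips) == 3
        row = table.set_index("key_phrase")
        assert row.loc["morphine", "n_snippets"] == 2
        assert row.loc["fentanyl", "n_snippets"] == 1
        assert row.loc["morphine", "n_patients"] == 1

    def test_empty_input_gives_empty_table(self):
        assert len(o.count_key_phrase_occurrences([])) == 0

    def test_synthetic_corpus_counts_match_generator_plan(
        self, lexicon, separable_corpus
    ):
        snippets, _, gold = separable_corpus
        table = o.count_key_phrase_occurrences(snippets)
        assert table["n_snippets"].sum() == gold["expected_snippets"].sum()
        implanted = gold["key_phrase"].value_counts()
        counted = table.set_index("key_phrase")["n_snippets"]
        for phrase, n in implanted.items():
            # single-word pool phrases map one-to-one onto snippets
            assert counted[phrase] == n
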