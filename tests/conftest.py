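"""Shared fixtures: default lexicon/library and a separable toy pipeline.

The separable corpus (2,000 implanted snippets, fixed seed) and the model
trained on it are session-scoped because several suites exercise the same
trained cascade.
"""

import pytest

import opionlp as o


@pytest.fixture(scope="session")
def lexicon():
    return o.load_lexicon()


@pytest.fixture(scope="session")
def library():
    return o.load_pattern_library()


@pytest.fixture(scope="session")
def separable_corpus(lexicon):
    """(snippets, labelled pairs, gold frame) for a 2,000-snippet corpus."""
    plan = o.CorpusPlan(
        n_patients=1000, notes_per_patient=2, implant_rate=1.0,
        positive_rate=0.5, seed=42,
    )
    notes, gold = o.generate_corpus(plan, lexicon)
    snippets = []
    for rec in notes.to_dict(orient="records"):
        snippets.extend(
            o.extract_snippets(rec["text"], lexicon, rec["note_id"], rec["patient_id"])
        )
    labelled = o.label_snippets(snippets, gold)
    return snippets, labelled, gold


@pytest.fixture(scope="session")
def trained(separable_corpus):
    _, labelled, _ = separable_corpus
    return o.train(labelled, seed=1)
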