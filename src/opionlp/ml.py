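"""SVM snippet classifier with lexically filtered n-gram + position features.

Snippets the rule tiers abstain on are classified by a linear support
vector machine. Text is preprocessed by lowercasing, whitespace
tokenization, and removal of non-alphanumeric characters from each token.
Features are raw counts of a vocabulary of unigrams (letters only) and
bigrams (first word letters only; second word letters and/or digits),
selected by document frequency, plus one scalar: the token index of the key
phrase's first word in the preprocessed snippet.

The three-class annotation scheme (positive / suspected / negative)
collapses to binary before training: suspected counts as positive.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
from scipy import sparse
from sklearn.model_selection import train_test_split
from sklearn.svm import LinearSVC

from .evaluation import ConfusionCounts, metrics as compute_metrics
from .lexicon import Snippet

LABELS = ("positive", "suspected", "negative")
_UNIGRAM = re.compile(r"^[a-z]+$")
_SECOND_WORD = re.compile(r"^[a-z0-9]+$")
_NON_ALNUM = re.compile(r"[^a-z0-9]+")

#: (snippet, label) pairs; labels from the 3-class annotation scheme
TrainingCorpus = Sequence[tuple[Snippet, str]]


def preprocess(text: str) -> list[str]:
    """Lowercase, whitespace-tokenize, strip non-alphanumerics per token.

    Tokens emptied by the stripping are dropped:
    ``"Opioid abuse (ICD-9 304.00)"`` -> ``["opioid","abuse","icd9","30400"]``.
    """
    out = []
    for tok in text.lower().split():
        tok = _NON_ALNUM.sub("", tok)
        if tok:
            out.append(tok)
    return out


def merge_suspected(label: str) -> str:
    """Collapse the 3-class annotation to binary (suspected -> positive)."""
    if label not in LABELS:
        raise ValueError(f"unknown label {label!r} (expected one of {LABELS})")
    return "positive" if label in ("positive", "suspected") else "negative"


@dataclass(frozen=True)
class FeatureSpec:
    """n-gram vocabulary (lexically filtered) and featurization options."""

    unigram_vocab: tuple[str, ...]
    bigram_vocab: tuple[tuple[str, str], ...]
    include_position: bool = True
    min_document_frequency: int = 1

    def __post_init__(self) -> None:
        for u in self.unigram_vocab:
            if not _UNIGRAM.match(u):
                raise ValueError(f"unigram {u!r} is not letters-only")
        for a, b in self.bigram_vocab:
            if not _UNIGRAM.match(a) or not _SECOND_WORD.match(b):
                raise ValueError(f"bigram {(a, b)!r} fails the lexical filter")

    @property
    def n_features(self) -> int:
        return len(self.unigram_vocab) + len(self.bigram_vocab) + int(self.include_position)


def build_feature_spec(
    corpus: TrainingCorpus,
    min_document_frequency: int = 1,
    include_position: bool = True,
) -> FeatureSpec:
    """Collect the filtered n-gram vocabulary from a training corpus.

    Unigrams must be letters only; a bigram's first word letters only and
    its second word letters, digits, or both. n-grams below the document
    frequency threshold are dropped; the surviving vocabulary is sorted
    lexicographically so the spec is deterministic.
    """
    if not corpus:
        raise ValueError("cannot build a feature spec from an empty corpus")
    if min_document_frequency < 1:
        raise ValueError("min_document_frequency must be >= 1")
    uni_df: dict[str, int] = {}
    bi_df: dict[tuple[str, str], int] = {}
    for snippet, _ in corpus:
        toks = preprocess(snippet.text)
        for u in {t for t in toks if _UNIGRAM.match(t)}:
            uni_df[u] = uni_df.get(u, 0) + 1
        bigrams = {
            (a, b)
            for a, b in zip(toks, toks[1:])
            if _UNIGRAM.match(a) and _SECOND_WORD.match(b)
        }
        for bg in bigrams:
            bi_df[bg] = bi_df.get(bg, 0) + 1
    unigrams = tuple(sorted(u for u, n in uni_df.items() if n >= min_document_frequency))
    bigrams_v = tuple(sorted(b for b, n in bi_df.items() if n >= min_document_frequency))
    if not unigrams and not bigrams_v:
        raise ValueError(
            "empty vocabulary: no n-gram reaches document frequency "
            f"{min_document_frequency} in a corpus of {len(corpus)} snippets"
        )
    return FeatureSpec(unigrams, bigrams_v, include_position, min_document_frequency)


def key_phrase_position(snippet: Snippet) -> int:
    """Token index of the key phrase's first word after preprocessing."""
    return len(preprocess(" ".join(snippet.tokens_before)))


def featurize(snippet: Snippet, spec: FeatureSpec) -> np.ndarray:
    """Dense feature vector: n-gram counts in vocabulary order + position."""
    toks = preprocess(snippet.text)
    vec = np.zeros(spec.n_features, dtype=np.float64)
    uni_index = {u: i for i, u in enumerate(spec.unigram_vocab)}
    bi_index = {b: len(uni_index) + i for i, b in enumerate(spec.bigram_vocab)}
    for t in toks:
        j = uni_index.get(t)
        if j is not None:
            vec[j] += 1
    for bg in zip(toks, toks[1:]):
        j = bi_index.get(bg)
        if j is not None:
            vec[j] += 1
    if spec.include_position:
        vec[-1] = key_phrase_position(snippet)
    return vec


def featurize_batch(snippets: Sequence[Snippet], spec: FeatureSpec) -> sparse.csr_matrix:
    uni_index = {u: i for i, u in enumerate(spec.unigram_vocab)}
    bi_index = {b: len(uni_index) + i for i, b in enumerate(spec.bigram_vocab)}
    rows, cols, vals = [], [], []
    for r, s in enumerate(snippets):
        toks = preprocess(s.text)
        counts: dict[int, float] = {}
        for t in toks:
            j = uni_index.get(t)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        for bg in zip(toks, toks[1:]):
            j = bi_index.get(bg)
            if j is not None:
                counts[j] = counts.get(j, 0) + 1
        if spec.include_position:
            counts[spec.n_features - 1] = key_phrase_position(s)
        for j, v in counts.items():
            rows.append(r)
            cols.append(j)
            vals.append(v)
    return sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(snippets), spec.n_features)
    )


@dataclass
class TrainedTextModel:
    """A fitted linear SVM plus everything needed to reproduce predictions."""

    feature_spec: FeatureSpec
    classifier: Optional[LinearSVC]
    random_seed: int
    svm_params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class TrainResult:
    model: TrainedTextModel
    metrics: dict
    held_out: tuple[tuple[Snippet, str], ...]  # binary-labelled 20% split


def train(
    corpus: TrainingCorpus,
    spec: Optional[FeatureSpec] = None,
    split_fraction: float = 0.8,
    seed: int = 0,
    min_document_frequency: int = 2,
) -> TrainResult:
    """Fit the SVM on a stratified train split and score the held-out rest.

    Suspected labels are merged into positive before splitting. When no
    feature spec is supplied one is built from the training split only, so
    the held-out metrics are computed on genuinely unseen data.
    """
    if not 0 < split_fraction < 1:
        raise ValueError("split_fraction must be in (0, 1)")
    pairs = [(s, merge_suspected(lab)) for s, lab in corpus]
    labels = [lab for _, lab in pairs]
    counts = {lab: labels.count(lab) for lab in set(labels)}
    if len(counts) < 2:
        raise ValueError(f"training corpus has a single class: {counts}")
    if min(counts.values()) < 2:
        raise ValueError(f"need >= 2 examples per class, got {counts}")
    idx = np.arange(len(pairs))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=1.0 - split_fraction,
        random_state=seed,
        stratify=labels,
    )
    train_pairs = [pairs[i] for i in train_idx]
    test_pairs = [pairs[i] for i in test_idx]
    if spec is None:
        spec = build_feature_spec(train_pairs, min_document_frequency)
    clf = LinearSVC(random_state=seed, max_iter=10000)
    X = featurize_batch([s for s, _ in train_pairs], spec)
    clf.fit(X, [lab for _, lab in train_pairs])
    model = TrainedTextModel(spec, clf, seed, clf.get_params())

    preds = predict_batch(model, [s for s, _ in test_pairs])
    gold = [lab for _, lab in test_pairs]
    cc = ConfusionCounts.from_labels(gold, preds)
    m = compute_metrics(cc)
    result_metrics = {
        "sensitivity": m.sensitivity,
        "specificity": m.specificity,
        "ppv": m.ppv,
        "accuracy": m.accuracy,
        "n_train": len(train_pairs),
        "n_test": len(test_pairs),
        "n_unigrams": len(spec.unigram_vocab),
        "n_bigrams": len(spec.bigram_vocab),
    }
    return TrainResult(model, result_metrics, tuple(test_pairs))


def predict(model: TrainedTextModel, snippet: Snippet) -> str:
    """Deterministic binary label for one snippet."""
    if model.classifier is None:
        raise ValueError("model has not been trained")
    return str(model.classifier.predict(featurize_batch([snippet], model.feature_spec))[0])


def predict_batch(model: TrainedTextModel, snippets: Sequence[Snippet]) -> list[str]:
    if model.classifier is None:
        raise ValueError("model has not been trained")
    if not snippets:
        return []
    X = featurize_batch(snippets, model.feature_spec)
    return [str(p) for p in model.classifier.predict(X)]


def save_model(model: TrainedTextModel, path: str | Path, metrics: Optional[dict] = None) -> None:
    """Persist the fitted SVM plus a JSON sidecar with the feature spec."""
    path = Path(path)
    joblib.dump(model.classifier, path)
    sidecar = {
        "format_version": 1,
        "random_seed": model.random_seed,
        "include_position": model.feature_spec.include_position,
        "min_document_frequency": model.feature_spec.min_document_frequency,
        "unigram_vocab": list(model.feature_spec.unigram_vocab),
        "bigram_vocab": [list(b) for b in model.feature_spec.bigram_vocab],
        "metrics": metrics or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1), "utf-8"
    )


def load_model(path: str | Path) -> TrainedTextModel:
    path = Path(path)
    clf = joblib.load(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text("utf-8"))
    spec = FeatureSpec(
        tuple(sidecar["unigram_vocab"]),
        tuple(tuple(b) for b in sidecar["bigram_vocab"]),
        sidecar["include_position"],
        sidecar["min_document_frequency"],
    )
    return TrainedTextModel(spec, clf, sidecar["random_seed"], clf.get_params())
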