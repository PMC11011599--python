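"""Key-phrase lexicon and fixed-window snippet extraction.

The unit of classification throughout the package is the *snippet*: one
occurrence of a key phrase together with up to 50 words of context on each
side of it in the note. Key phrases are short (1-2 word) opioid-related
terms — generic and trade drug names plus concept phrases such as
"withdrawal" or "opioid dependence". The default lexicon ships 36 phrases.

Tokenization for windowing splits on runs of whitespace and leaves
punctuation attached to tokens, so the snippet text handed to the rule
classifier is the raw clinical text. Phrase matching is case-insensitive
and ignores punctuation hugging a token ("oxycodone," matches "oxycodone").
At a given token position the longest matching phrase wins; overlapping
matches that start at different positions each yield their own snippet.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

#: context window, in whitespace tokens, on each side of the key phrase
WINDOW = 50

VALID_CATEGORIES = ("drug_name", "other")

_EDGE_PUNCT = re.compile(r"^\W+|\W+$")


def _norm_token(token: str) -> str:
    """Lowercase a raw token and strip punctuation from its edges."""
    return _EDGE_PUNCT.sub("", token.lower())


def _norm_phrase(phrase: str) -> str:
    return " ".join(phrase.lower().split())


@dataclass(frozen=True)
class KeyPhraseLexicon:
    """An ordered set of key phrases with a category per phrase."""

    phrases: tuple[str, ...]
    categories: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.phrases:
            raise ValueError("lexicon must contain at least one phrase")
        seen = Counter(self.phrases)
        dupes = [p for p, n in seen.items() if n > 1]
        if dupes:
            raise ValueError(f"duplicate phrases in lexicon: {sorted(dupes)}")
        for p in self.phrases:
            if not re.fullmatch(r"[a-z0-9]+( [a-z0-9]+)?", p):
                raise ValueError(
                    f"phrase {p!r} is not a 1-2 word lowercase alphanumeric phrase"
                )
        for p, c in self.categories.items():
            if c not in VALID_CATEGORIES:
                raise ValueError(f"invalid category {c!r} for phrase {p!r}")

    def __len__(self) -> int:
        return len(self.phrases)

    def __contains__(self, phrase: str) -> bool:
        return _norm_phrase(phrase) in self.phrases

    def category(self, phrase: str) -> str:
        return self.categories.get(_norm_phrase(phrase), "other")

    def drug_names(self) -> tuple[str, ...]:
        return tuple(p for p in self.phrases if self.category(p) == "drug_name")

    def phrase_tokens(self) -> list[tuple[str, ...]]:
        """Phrases as token tuples, longest first (for longest-match-wins)."""
        toks = [tuple(p.split()) for p in self.phrases]
        return sorted(toks, key=len, reverse=True)


def load_lexicon(path: Optional[str | Path] = None) -> KeyPhraseLexicon:
    """Load a lexicon file (one phrase per line, optional tab + category).

    With no path, the default 36-phrase lexicon shipped with the package is
    returned. Lines starting with ``#`` and blank lines are ignored.
    """
    if path is None:
        text = (
            resources.files("opionlp").joinpath("data/key_phrases.txt").read_text("utf-8")
        )
        source = "<default lexicon>"
    else:
        text = Path(path).read_text("utf-8")
        source = str(path)

    phrases: list[str] = []
    categories: dict[str, str] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = [p.strip() for p in line.split("\t")]
        phrase = _norm_phrase(parts[0])
        if len(parts) > 2:
            raise ValueError(f"{source}:{lineno}: too many fields")
        if len(parts) == 2:
            if parts[1] not in VALID_CATEGORIES:
                raise ValueError(
                    f"{source}:{lineno}: malformed category {parts[1]!r} "
                    f"(expected one of {VALID_CATEGORIES})"
                )
            categories[phrase] = parts[1]
        if phrase in phrases:
            raise ValueError(f"{source}:{lineno}: duplicate phrase {phrase!r}")
        phrases.append(phrase)
    if not phrases:
        raise ValueError(f"{source}: lexicon file contains no phrases")
    return KeyPhraseLexicon(tuple(phrases), categories)


@dataclass(frozen=True)
class Snippet:
    """One key-phrase occurrence with its raw-token context window.

    ``tokens_before``/``tokens_after`` hold at most :data:`WINDOW` raw
    (whitespace-delimited) tokens each; ``matched_tokens`` are the raw tokens
    the key phrase matched, punctuation included.
    """

    key_phrase: str
    tokens_before: tuple[str, ...]
    matched_tokens: tuple[str, ...]
    tokens_after: tuple[str, ...]
    note_id: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        if len(self.tokens_before) > WINDOW or len(self.tokens_after) > WINDOW:
            raise ValueError(f"context windows are limited to {WINDOW} tokens")
        if not self.matched_tokens:
            raise ValueError("snippet must contain the matched key-phrase tokens")

    @property
    def key_phrase_token_index(self) -> int:
        """Index of the key phrase's first token within the snippet tokens."""
        return len(self.tokens_before)

    @property
    def tokens(self) -> tuple[str, ...]:
        return self.tokens_before + self.matched_tokens + self.tokens_after

    @property
    def text(self) -> str:
        return " ".join(self.tokens)


def extract_snippets(
    note_text: str,
    lexicon: KeyPhraseLexicon,
    note_id: str = "",
    patient_id: str = "",
) -> list[Snippet]:
    """Extract one snippet per key-phrase match position in ``note_text``.

    At each token position the longest phrase starting there wins (a match
    of "opioid dependence" suppresses "opioid" at the same position but not
    a later "dependence"). Windows are truncated, never padded, at note
    boundaries. Empty text yields an empty list.
    """
    tokens = note_text.split()
    if not tokens:
        return []
    norm = [_norm_token(t) for t in tokens]
    by_len = lexicon.phrase_tokens()
    out: list[Snippet] = []
    n = len(tokens)
    for i in range(n):
        for ptoks in by_len:
            k = len(ptoks)
            if i + k <= n and tuple(norm[i : i + k]) == ptoks:
                out.append(
                    Snippet(
                        key_phrase=" ".join(ptoks),
                        tokens_before=tuple(tokens[max(0, i - WINDOW) : i]),
                        matched_tokens=tuple(tokens[i : i + k]),
                        tokens_after=tuple(tokens[i + k : i + k + WINDOW]),
                        note_id=note_id,
                        patient_id=patient_id,
                    )
                )
                break  # longest match wins at this position
    return out


def snippet_from_text(
    text: str,
    key_phrase: str,
    note_id: str = "",
    patient_id: str = "",
) -> Snippet:
    """Build a snippet from free text known to contain ``key_phrase``.

    Used when reading annotated snippet files, where only the text and the
    key phrase are recorded. The first occurrence anchors the window.
    """
    tokens = text.split()
    norm = [_norm_token(t) for t in tokens]
    ptoks = tuple(_norm_phrase(key_phrase).split())
    k = len(ptoks)
    for i in range(len(tokens) - k + 1):
        if tuple(norm[i : i + k]) == ptoks:
            return Snippet(
                key_phrase=" ".join(ptoks),
                tokens_before=tuple(tokens[max(0, i - WINDOW) : i]),
                matched_tokens=tuple(tokens[i : i + k]),
                tokens_after=tuple(tokens[i + k : i + k + WINDOW]),
                note_id=note_id,
                patient_id=patient_id,
            )
    raise ValueError(f"key phrase {key_phrase!r} not found in text")


def count_key_phrase_occurrences(snippets: Iterable[Snippet]) -> pd.DataFrame:
    """Tally snippets per key phrase with distinct-patient counts.

    Returns a frame with columns ``key_phrase``, ``n_snippets``,
    ``n_patients``; ``n_snippets`` sums to the number of input snippets.
    """
    rows: dict[str, list] = {}
    patients: dict[str, set] = {}
    for s in snippets:
        rows[s.key_phrase] = rows.get(s.key_phrase, 0) + 1
        patients.setdefault(s.key_phrase, set()).add(s.patient_id)
    table = pd.DataFrame(
        {
            "key_phrase": sorted(rows),
            "n_snippets": [rows[p] for p in sorted(rows)],
            "n_patients": [len(patients[p]) for p in sorted(rows)],
        }
    )
    return table
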