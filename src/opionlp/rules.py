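"""Tiered regular-expression snippet classifier (sequential voting).

Snippets are tested against four ordered pattern tiers; the first tier with
any matching pattern decides the label and later tiers are never consulted:

1. ``absolute_positive`` -> positive (unambiguous current problematic use)
2. ``canceling``         -> negative (positive-sounding but not current)
3. ``general_positive``  -> positive (bare concept mentions)
4. ``neutral``           -> negative (not about the patient's own use)

A snippet matching no tier is an *abstention* and falls through to the
machine-learning classifier in the cascade. Matching is done on the raw
snippet window text, lowercased but otherwise unmodified.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .lexicon import Snippet

TIER_ORDER = ("absolute_positive", "canceling", "general_positive", "neutral")
TIER_LABEL = {
    "absolute_positive": "positive",
    "canceling": "negative",
    "general_positive": "positive",
    "neutral": "negative",
}

POSITIVE = "positive"
NEGATIVE = "negative"
ABSTAIN = "abstain"


@dataclass
class PatternLibrary:
    """Four ordered tiers of regular-expression patterns."""

    absolute_positive: list[str] = field(default_factory=list)
    canceling: list[str] = field(default_factory=list)
    general_positive: list[str] = field(default_factory=list)
    neutral: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not any(self.tier(t) for t in TIER_ORDER):
            raise ValueError("pattern library must contain at least one pattern")
        self._compiled: dict[str, list[re.Pattern]] = {}
        for tier in TIER_ORDER:
            compiled = []
            for i, pat in enumerate(self.tier(tier), start=1):
                try:
                    compiled.append(re.compile(pat))
                except re.error as exc:
                    raise ValueError(
                        f"invalid regex in tier {tier!r}, pattern {i}: {pat!r} ({exc})"
                    ) from exc
            self._compiled[tier] = compiled

    def tier(self, name: str) -> list[str]:
        if name not in TIER_ORDER:
            raise KeyError(f"unknown tier {name!r}")
        return getattr(self, name)

    def compiled(self, name: str) -> list[re.Pattern]:
        return self._compiled[name]

    def to_dict(self) -> dict[str, list[str]]:
        return {t: list(self.tier(t)) for t in TIER_ORDER}


@dataclass(frozen=True)
class RuleDecision:
    """Outcome of the sequential tier vote for one snippet."""

    label: str  # positive | negative | abstain
    tier: str  # tier name, or "none" on abstention
    matched_pattern: str = ""

    def __post_init__(self) -> None:
        if self.label == ABSTAIN:
            if self.tier != "none" or self.matched_pattern:
                raise ValueError("abstention carries no tier or pattern")
        elif TIER_LABEL.get(self.tier) != self.label:
            raise ValueError(f"label {self.label!r} inconsistent with tier {self.tier!r}")


def classify_by_rules(
    snippet: Union[Snippet, str], library: PatternLibrary
) -> RuleDecision:
    """Classify a snippet by the first tier containing a matching pattern.

    Tiers are tried strictly in :data:`TIER_ORDER`; pattern order within a
    tier affects only which pattern is reported, never the label. With no
    match anywhere the decision is an abstention.
    """
    text = (snippet.text if isinstance(snippet, Snippet) else snippet).lower()
    for tier in TIER_ORDER:
        for pat in library.compiled(tier):
            if pat.search(text):
                return RuleDecision(TIER_LABEL[tier], tier, pat.pattern)
    return RuleDecision(ABSTAIN, "none")


def load_pattern_library(path: Optional[str | Path] = None) -> PatternLibrary:
    """Load a YAML pattern library; with no path, the shipped seed library.

    The file maps tier names to lists of regex strings. Unknown tiers and
    non-compiling patterns raise ``ValueError`` naming the offender.
    """
    if path is None:
        text = resources.files("opionlp").joinpath("data/patterns.yml").read_text("utf-8")
        source = "<seed library>"
    else:
        text = Path(path).read_text("utf-8")
        source = str(path)
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{source}: pattern library must be a mapping of tiers")
    unknown = set(data) - set(TIER_ORDER)
    if unknown:
        raise ValueError(f"{source}: unknown tiers {sorted(unknown)}")
    tiers = {t: [str(p) for p in (data.get(t) or [])] for t in TIER_ORDER}
    return PatternLibrary(**tiers)


def save_pattern_library(library: PatternLibrary, path: str | Path) -> None:
    Path(path).write_text(
        yaml.safe_dump(library.to_dict(), sort_keys=False, default_flow_style=False),
        "utf-8",
    )
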