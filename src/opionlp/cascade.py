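"""Rules-then-SVM cascade, patient-level aggregation, and ICD grouping.

Every snippet first goes through the tiered rule classifier; only snippets
the rules abstain on are handed to the SVM, so coverage is always 100%.
Patients are then assigned to three mutually exclusive analysis groups:

* ``ALL_ICD`` — any qualifying opioid-use-disorder ICD code
  (ICD-9-CM 304.00, 304.70, 305.50; any ICD-10-CM F11.x),
* ``NLP_ONLY`` — at least one positive snippet but no qualifying code,
* ``NO_PROBLEMATIC_USE`` — neither.

The *overlap* subgroup (coded patients who also have positive snippets,
"NLP/ICD") is reported alongside; by construction its size equals
(all NLP-positive patients) − |NLP_ONLY|.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .lexicon import KeyPhraseLexicon, Snippet
from .ml import TrainedTextModel, predict_batch
from .rules import ABSTAIN, PatternLibrary, RuleDecision, classify_by_rules

GROUP_ALL_ICD = "ALL_ICD"
GROUP_NLP_ONLY = "NLP_ONLY"
GROUP_NONE = "NO_PROBLEMATIC_USE"
GROUP_NLP_ICD = "NLP_ICD"  # overlap subgroup of ALL_ICD

QUALIFYING_ICD9 = frozenset({"304.00", "304.70", "305.50"})
QUALIFYING_ICD10_PREFIX = "F11"


@dataclass(frozen=True)
class ClassifiedSnippet:
    snippet: Snippet
    label: str  # positive | negative
    method: str  # rule | svm
    tier: str = ""  # tier name when method == rule

    def __post_init__(self) -> None:
        if (self.method == "rule") != bool(self.tier):
            raise ValueError("tier must be set exactly when method is 'rule'")


@dataclass
class PatientRecord:
    """Structured data for one patient: codes, covariates, index date."""

    patient_id: str
    icd_codes: list[tuple[str, Optional[dt.date]]] = field(default_factory=list)
    attributes: dict = field(default_factory=dict)
    index_date: Optional[dt.date] = None


@dataclass(frozen=True)
class GroupAssignment:
    patient_id: str
    group: str
    nlp_positive: bool
    icd_positive: bool

    def __post_init__(self) -> None:
        expected = (
            GROUP_ALL_ICD
            if self.icd_positive
            else (GROUP_NLP_ONLY if self.nlp_positive else GROUP_NONE)
        )
        if self.group != expected:
            raise ValueError(f"group {self.group!r} inconsistent with flags")

    @property
    def in_overlap(self) -> bool:
        return self.icd_positive and self.nlp_positive


def classify_snippet(
    snippet: Snippet, library: PatternLibrary, model: TrainedTextModel
) -> ClassifiedSnippet:
    """Rule decision when any tier matches; otherwise the SVM's label."""
    decision: RuleDecision = classify_by_rules(snippet, library)
    if decision.label != ABSTAIN:
        return ClassifiedSnippet(snippet, decision.label, "rule", decision.tier)
    from .ml import predict

    return ClassifiedSnippet(snippet, predict(model, snippet), "svm")


def classify_snippets(
    snippets: Sequence[Snippet], library: PatternLibrary, model: TrainedTextModel
) -> list[ClassifiedSnippet]:
    """Batch cascade; one labelled snippet out per snippet in (100% coverage)."""
    rule_out: dict[int, ClassifiedSnippet] = {}
    abstained: list[int] = []
    for i, s in enumerate(snippets):
        d = classify_by_rules(s, library)
        if d.label == ABSTAIN:
            abstained.append(i)
        else:
            rule_out[i] = ClassifiedSnippet(s, d.label, "rule", d.tier)
    svm_labels = predict_batch(model, [snippets[i] for i in abstained])
    for i, lab in zip(abstained, svm_labels):
        rule_out[i] = ClassifiedSnippet(snippets[i], lab, "svm")
    return [rule_out[i] for i in range(len(snippets))]


def is_icd_positive(codes: Iterable[str]) -> bool:
    """True iff any code is 304.00/304.70/305.50 or starts with F11.

    F11 is treated as a code family: F11 alone is a category header in
    ICD-10-CM, so any F11.x qualifies. Codes are compared uppercase with
    dots preserved.
    """
    for code in codes:
        c = str(code).strip().upper()
        if c in QUALIFYING_ICD9 or c.startswith(QUALIFYING_ICD10_PREFIX):
            return True
    return False


def assign_groups(
    patients: Sequence[PatientRecord],
    classified: Sequence[ClassifiedSnippet],
) -> list[GroupAssignment]:
    """Partition the cohort into ALL_ICD / NLP_ONLY / NO_PROBLEMATIC_USE.

    A patient is NLP-positive iff they have >= 1 positive snippet. Snippets
    referencing a patient absent from ``patients`` are an error.
    """
    known = {p.patient_id for p in patients}
    orphans = sorted(
        {c.snippet.patient_id for c in classified if c.snippet.patient_id not in known}
    )
    if orphans:
        raise ValueError(f"classified snippets reference unknown patients: {orphans}")
    nlp_pos = {c.snippet.patient_id for c in classified if c.label == "positive"}
    out = []
    for p in patients:
        icd = is_icd_positive(code for code, _ in p.icd_codes)
        nlp = p.patient_id in nlp_pos
        group = GROUP_ALL_ICD if icd else (GROUP_NLP_ONLY if nlp else GROUP_NONE)
        out.append(GroupAssignment(p.patient_id, group, nlp, icd))
    return out


def group_sizes(assignments: Sequence[GroupAssignment]) -> dict[str, int]:
    """Group sizes plus the NLP/ICD overlap and total-NLP-positive counts."""
    sizes = {GROUP_ALL_ICD: 0, GROUP_NLP_ONLY: 0, GROUP_NONE: 0}
    overlap = nlp_total = 0
    for a in assignments:
        sizes[a.group] += 1
        overlap += a.in_overlap
        nlp_total += a.nlp_positive
    sizes["overlap"] = overlap
    sizes["nlp_positive_total"] = nlp_total
    return sizes


def nlp_icd_overlap(n_nlp_positive: int, n_nlp_only: int) -> int:
    """Overlap size implied by the partition: NLP-positive − NLP-only."""
    if n_nlp_only > n_nlp_positive:
        raise ValueError("NLP_ONLY cannot exceed the NLP-positive total")
    return n_nlp_positive - n_nlp_only


def compute_index_dates(
    patients: Sequence[PatientRecord],
    classified: Sequence[ClassifiedSnippet],
    note_dates: Optional[Mapping[str, dt.date]] = None,
) -> None:
    """Set each patient's index date in place.

    The index date is the earliest documentation of problematic opioid use:
    min(first qualifying ICD code date, first positive-snippet note date).
    Same-day ties resolve to the ICD date. Patients with neither keep
    ``index_date=None``.
    """
    note_dates = note_dates or {}
    first_pos: dict[str, dt.date] = {}
    for c in classified:
        if c.label != "positive":
            continue
        d = note_dates.get(c.snippet.note_id)
        if d is None:
            continue
        pid = c.snippet.patient_id
        if pid not in first_pos or d < first_pos[pid]:
            first_pos[pid] = d
    for p in patients:
        icd_dates = [
            d
            for code, d in p.icd_codes
            if d is not None and is_icd_positive([code])
        ]
        icd_first = min(icd_dates) if icd_dates else None
        nlp_first = first_pos.get(p.patient_id)
        if icd_first is not None and (nlp_first is None or icd_first <= nlp_first):
            p.index_date = icd_first
        else:
            p.index_date = nlp_first


def _members(
    assignments: Sequence[GroupAssignment], group: str
) -> set[str]:
    if group == GROUP_NLP_ICD:
        return {a.patient_id for a in assignments if a.in_overlap}
    return {a.patient_id for a in assignments if a.group == group}


def tally_positive_patterns(
    classified: Sequence[ClassifiedSnippet],
    lexicon: KeyPhraseLexicon,
    assignments: Sequence[GroupAssignment],
    groups: Sequence[str] = (GROUP_NLP_ONLY, GROUP_NLP_ICD),
) -> pd.DataFrame:
    """Per-group counts of patients with positive drug-name vs other-phrase
    snippets, and mean/SD of positive snippets per patient.

    A patient with positive snippets of both kinds is counted in both
    columns. Mean/SD (sample SD) run over the group's patients that have at
    least one positive snippet.
    """
    drug_pats: dict[str, set] = {}
    other_pats: dict[str, set] = {}
    pos_counts: dict[str, int] = {}
    for c in classified:
        if c.label != "positive":
            continue
        pid = c.snippet.patient_id
        pos_counts[pid] = pos_counts.get(pid, 0) + 1
        bucket = (
            drug_pats if lexicon.category(c.snippet.key_phrase) == "drug_name" else other_pats
        )
        bucket.setdefault(pid, set()).add(c.snippet.key_phrase)
    rows = []
    for g in groups:
        members = _members(assignments, g)
        with_pos = [pos_counts[p] for p in members if p in pos_counts]
        rows.append(
            {
                "group": g,
                "patients_drug_name_positive": sum(1 for p in members if p in drug_pats),
                "patients_other_phrase_positive": sum(1 for p in members if p in other_pats),
                "mean_positive_snippets": float(np.mean(with_pos)) if with_pos else 0.0,
                "sd_positive_snippets": (
                    float(np.std(with_pos, ddof=1)) if len(with_pos) > 1 else 0.0
                ),
            }
        )
    return pd.DataFrame(rows)
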