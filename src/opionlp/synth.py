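"""Synthetic note corpora and patient cohorts with known ground truth.

Real clinical notes containing opioid documentation cannot be shared, so
every module here is exercised on synthetic data:

* :func:`generate_corpus` writes notes of neutral clinical filler into
  which key-phrase-bearing context templates are implanted. Each implanted
  context is drawn from a positive or a negative template bank (both
  paraphrasing the styles of documentation the classifier targets:
  problem-list entries, drug-seeking narratives, medication-direction
  lines, family-history mentions, ...), and the note-level gold label,
  template kind (rule-matched vs pattern-free), and expected snippet count
  are all recorded.
* :func:`generate_cohort` draws patient covariate tables per analysis
  group — Bernoulli for binary flags and categorical levels, 0-truncated
  Normal for age and encounter counts — plus an ICD code table in which a
  configurable fraction of each group carries a qualifying OUD code.

Covariates are generated independently; the cohort comparison consumes
only marginal prevalences. Default prevalences/means are realistic values
for a veteran cohort stratified by documentation method.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .lexicon import KeyPhraseLexicon, load_lexicon

# ---------------------------------------------------------------------------
# note corpus generation
# ---------------------------------------------------------------------------

#: neutral clinical filler; must contain no key phrase and trip no rule tier
FILLER_WORDS = (
    "patient seen in clinic today for routine followup visit vital signs "
    "stable exam unremarkable plan discussed with care team will return in "
    "several weeks reviewed chart notes labs within normal limits no acute "
    "distress ambulating well diet and exercise counseling provided blood "
    "pressure rechecked heart regular lungs clear continues to work on goals"
).split()

#: positive-context templates; kind "rule" contexts are caught by the seed
#: pattern library, kind "ml" contexts carry only lexical cues for the SVM
POSITIVE_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("patient continues to struggle with {KEY} and is using daily", "rule"),
    ("[x] ongoing {KEY} misuse checked on intake questionnaire", "rule"),
    ("{KEY} treatment program notes heroin last used yesterday per patient report", "ml"),
    ("alludes to possibility of self medicating on the street with {KEY}", "ml"),
    ("would not receive prescription for {KEY} until next month taking additional doses was a patient safety issue", "ml"),
    ("ongoing misuse of {KEY} with escalating doses and cravings reported", "ml"),
)

NEGATIVE_TEMPLATES: tuple[tuple[str, str], ...] = (
    ("former {KEY} misuse years ago now resolved", "rule"),
    ("{KEY} 4 mg tab take one tablet every four hours when needed for pain", "rule"),
    ("sister abuses {KEY} per social history", "rule"),
    ("family hx of heavy drinking and {KEY} use by relatives", "rule"),
    ("was on {KEY} and tried to change but since she developed rash it was stopped", "ml"),
    ("patient requested no {KEY} at this visit", "ml"),
    ("continue tylenol and {KEY} as needed per home regimen", "ml"),
    ("tolerating {KEY} well no adverse effects noted at routine followup", "ml"),
)

NOTE_TYPES = ("primary care note", "emergency dept note", "mental health note", "nursing note")

_STUDY_START = dt.date(2012, 1, 1)
_STUDY_DAYS = (dt.date(2019, 12, 31) - _STUDY_START).days


def default_phrase_pool(lexicon: Optional[KeyPhraseLexicon] = None) -> tuple[str, ...]:
    """Implantable key phrases: single-word phrases plus drug names.

    The two-word concept phrases ("opioid dependence", "substance abuse",
    ...) are left out of the default pool: the rule library treats a bare
    occurrence of those phrases as positive evidence regardless of context,
    so implanting them into a negative-context template would put the
    template polarity and the intended rule behaviour at odds. Pass an
    explicit pool to override.
    """
    lexicon = lexicon or load_lexicon()
    return tuple(p for p in lexicon.phrases if " " not in p)


@dataclass(frozen=True)
class CorpusPlan:
    """Generation plan for a synthetic note corpus.

    ``implant_rate`` is the probability that a note carries an implanted
    key-phrase context (default mirrors a realistic share of notes that
    mention a key phrase at all); ``positive_rate`` the probability that an
    implanted context is positive (default mirrors a realistic positive
    fraction among key-phrase snippets, roughly one in five).
    """

    n_patients: int = 500
    notes_per_patient: Union[int, tuple[str, float]] = ("poisson", 3.0)
    filler_tokens: int = 120
    implant_rate: float = 0.043
    positive_rate: float = 0.214
    positive_context_templates: tuple[tuple[str, str], ...] = POSITIVE_TEMPLATES
    negative_context_templates: tuple[tuple[str, str], ...] = NEGATIVE_TEMPLATES
    phrases: Optional[tuple[str, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("implant_rate", "positive_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not self.positive_context_templates or not self.negative_context_templates:
            raise ValueError("template banks must be non-empty")
        for bank in (self.positive_context_templates, self.negative_context_templates):
            for text, kind in bank:
                if "{KEY}" not in text:
                    raise ValueError(f"template lacks a {{KEY}} placeholder: {text!r}")
                if kind not in ("rule", "ml"):
                    raise ValueError(f"template kind must be rule|ml, got {kind!r}")
        if self.n_patients < 1 or self.filler_tokens < 1:
            raise ValueError("n_patients and filler_tokens must be positive")


def _validate_templates(plan: CorpusPlan, lexicon: KeyPhraseLexicon) -> None:
    """Static template text must not itself contain a key phrase."""
    from .lexicon import extract_snippets

    for bank in (plan.positive_context_templates, plan.negative_context_templates):
        for text, _ in bank:
            stray = extract_snippets(text.replace("{KEY}", "zzzz"), lexicon)
            if stray:
                raise ValueError(
                    f"template contains key phrases outside {{KEY}}: {text!r} "
                    f"({[s.key_phrase for s in stray]})"
                )


def _expected_snippets(phrase: str, lexicon: KeyPhraseLexicon) -> int:
    """Snippets one implanted phrase yields: 1 + matches starting inside it.

    A two-word phrase whose second word is itself a key phrase (e.g.
    "opioid dependence" containing "dependence") produces an extra snippet
    at the later start position.
    """
    toks = phrase.split()
    extra = 0
    phrase_set = {tuple(p.split()) for p in lexicon.phrases}
    for j in range(1, len(toks)):
        for k in range(len(toks) - j, 0, -1):
            if tuple(toks[j : j + k]) in phrase_set:
                extra += 1
                break
    return 1 + extra


def _n_notes(rng: np.random.Generator, spec: Union[int, tuple[str, float]]) -> int:
    if isinstance(spec, int):
        return spec
    dist, param = spec
    if dist != "poisson":
        raise ValueError(f"unsupported notes-per-patient distribution {dist!r}")
    return max(1, int(rng.poisson(param)))


def generate_corpus(
    plan: CorpusPlan, lexicon: Optional[KeyPhraseLexicon] = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (notes, gold) frames, reproducible under ``plan.seed``.

    ``notes`` has columns note_id, patient_id, note_date, note_type, text;
    ``gold`` one row per implant with the note-level label, template kind,
    implanted key phrase, and the exact number of snippets extraction will
    produce from that note.
    """
    lexicon = lexicon or load_lexicon()
    _validate_templates(plan, lexicon)
    pool = plan.phrases if plan.phrases is not None else default_phrase_pool(lexicon)
    if not pool:
        raise ValueError("phrase pool is empty")
    for p in pool:
        if p not in lexicon:
            raise ValueError(f"pool phrase {p!r} is not in the lexicon")
    rng = np.random.default_rng(plan.seed)
    notes, gold = [], []
    note_seq = 0
    for i in range(plan.n_patients):
        pid = f"P{i:06d}"
        for _ in range(_n_notes(rng, plan.notes_per_patient)):
            note_seq += 1
            nid = f"N{note_seq:07d}"
            filler = list(rng.choice(FILLER_WORDS, size=plan.filler_tokens))
            date = _STUDY_START + dt.timedelta(days=int(rng.integers(0, _STUDY_DAYS + 1)))
            note_type = str(rng.choice(NOTE_TYPES))
            if rng.random() < plan.implant_rate:
                positive = rng.random() < plan.positive_rate
                bank = (
                    plan.positive_context_templates
                    if positive
                    else plan.negative_context_templates
                )
                t_idx = int(rng.integers(0, len(bank)))
                template, kind = bank[t_idx]
                phrase = str(pool[int(rng.integers(0, len(pool)))])
                context = template.replace("{KEY}", phrase).split()
                at = int(rng.integers(0, len(filler) + 1))
                tokens = filler[:at] + context + filler[at:]
                gold.append(
                    {
                        "note_id": nid,
                        "patient_id": pid,
                        "key_phrase": phrase,
                        "label": "positive" if positive else "negative",
                        "template_kind": kind,
                        "expected_snippets": _expected_snippets(phrase, lexicon),
                    }
                )
            else:
                tokens = filler
            notes.append(
                {
                    "note_id": nid,
                    "patient_id": pid,
                    "note_date": date.isoformat(),
                    "note_type": note_type,
                    "text": " ".join(tokens),
                }
            )
    return pd.DataFrame(notes), pd.DataFrame(gold)


def label_snippets(
    snippets: Sequence, gold: pd.DataFrame
) -> list[tuple]:
    """Attach note-level gold labels to extracted snippets by note id."""
    labels = dict(zip(gold["note_id"], gold["label"]))
    out = []
    for s in snippets:
        if s.note_id not in labels:
            raise ValueError(f"no gold label for note {s.note_id!r}")
        out.append((s, labels[s.note_id]))
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupSpec:
    """Marginal covariate distributions for one analysis group."""

    name: str
    n: int
    binary: dict[str, float] = field(default_factory=dict)
    categorical: dict[str, dict[str, float]] = field(default_factory=dict)
    continuous: dict[str, tuple[float, float]] = field(default_factory=dict)
    icd_positive: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.name!r}: n must be positive")
        for var, p in self.binary.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"group {self.name!r}: prevalence {p} for {var!r} not in [0,1]")
        for var, levels in self.categorical.items():
            probs = np.array(list(levels.values()), dtype=float)
            if (probs < 0).any() or not np.isclose(probs.sum(), 1.0, atol=1e-6):
                raise ValueError(f"group {self.name!r}: level probabilities of {var!r} must sum to 1")
        for var, (_, sd) in self.continuous.items():
            if sd < 0:
                raise ValueError(f"group {self.name!r}: SD of {var!r} must be >= 0")
        if not 0.0 <= self.icd_positive <= 1.0:
            raise ValueError(f"group {self.name!r}: icd_positive not in [0,1]")


@dataclass(frozen=True)
class CohortPlan:
    groups: tuple[GroupSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("cohort plan needs at least one group")


_COMORBIDITY_DEFAULTS = {
    # variable: (ALL_ICD, NLP_ONLY, NO_PROBLEMATIC_USE) prevalences
    "hypertension": (0.571, 0.535, 0.458),
    "diabetes": (0.221, 0.250, 0.204),
    "depression": (0.618, 0.411, 0.196),
    "ptsd": (0.396, 0.251, 0.108),
    "cancer": (0.090, 0.121, 0.129),
    "tobacco": (0.620, 0.311, 0.154),
    "alcohol": (0.609, 0.238, 0.092),
    "other_drug_addictions": (0.666, 0.186, 0.042),
    "tbi": (0.115, 0.070, 0.036),
    "anxiety": (0.397, 0.276, 0.141),
    "neck_pain": (0.394, 0.313, 0.182),
    "back_pain": (0.570, 0.472, 0.307),
    "prior_opioid_rx": (0.715, 0.516, 0.321),
    "concurrent_benzodiazepine_rx": (0.194, 0.101, 0.039),
}

_CATEGORICAL_DEFAULTS = {
    "gender": {
        "ALL_ICD": {"M": 0.93, "F": 0.07},
        "NLP_ONLY": {"M": 0.82, "F": 0.18},
        "NO_PROBLEMATIC_USE": {"M": 0.849, "F": 0.151},
    },
    "marital_status": {
        "ALL_ICD": {"married": 0.257, "divorced": 0.316, "never_married": 0.265,
                    "widowed": 0.045, "separated": 0.113, "other": 0.004},
        "NLP_ONLY": {"married": 0.385, "divorced": 0.258, "never_married": 0.228,
                     "widowed": 0.051, "separated": 0.065, "other": 0.013},
        "NO_PROBLEMATIC_USE": {"married": 0.502, "divorced": 0.171, "never_married": 0.156,
                               "widowed": 0.069, "separated": 0.032, "other": 0.070},
    },
    "race": {
        "ALL_ICD": {"black": 0.597, "white": 0.357, "asian": 0.001,
                    "pacific_islander": 0.004, "native_american": 0.005, "unknown": 0.036},
        "NLP_ONLY": {"black": 0.540, "white": 0.366, "asian": 0.010,
                     "pacific_islander": 0.005, "native_american": 0.007, "unknown": 0.072},
        "NO_PROBLEMATIC_USE": {"black": 0.282, "white": 0.514, "asian": 0.012,
                               "pacific_islander": 0.005, "native_american": 0.005, "unknown": 0.182},
    },
    "ethnicity": {
        "ALL_ICD": {"not_hispanic": 0.965, "hispanic": 0.015, "unknown": 0.020},
        "NLP_ONLY": {"not_hispanic": 0.923, "hispanic": 0.029, "unknown": 0.048},
        "NO_PROBLEMATIC_USE": {"not_hispanic": 0.806, "hispanic": 0.029, "unknown": 0.165},
    },
}

_CONTINUOUS_DEFAULTS = {
    "age": {"ALL_ICD": (53.3, 12.2), "NLP_ONLY": (55.4, 16.1),
            "NO_PROBLEMATIC_USE": (58.8, 18.7)},
    "outpatient_encounters": {"ALL_ICD": (50.9, 49.8), "NLP_ONLY": (33.4, 31.3),
                              "NO_PROBLEMATIC_USE": (16.2, 23.2)},
}

_DEFAULT_GROUP_NS = {"ALL_ICD": 6997, "NLP_ONLY": 57331, "NO_PROBLEMATIC_USE": 158043}

QUALIFYING_CODES = ("304.00", "304.70", "305.50", "F11.20", "F11.10", "F11.90")
NON_QUALIFYING_CODES = ("I10", "E11.9", "M54.5", "F32.9", "F10.20", "305.1")


def default_cohort_plan(
    n_per_group: Optional[int] = None, seed: int = 0
) -> CohortPlan:
    """Three-group plan with realistic default prevalences and sizes.

    Group sizes default to a veteran cohort's observed split across the
    three documentation groups; pass ``n_per_group`` for equal-sized groups
    (e.g. in recovery experiments).
    """
    groups = []
    for gname in ("ALL_ICD", "NLP_ONLY", "NO_PROBLEMATIC_USE"):
        groups.append(
            GroupSpec(
                name=gname,
                n=n_per_group if n_per_group is not None else _DEFAULT_GROUP_NS[gname],
                binary={v: ps[("ALL_ICD", "NLP_ONLY", "NO_PROBLEMATIC_USE").index(gname)]
                        for v, ps in _COMORBIDITY_DEFAULTS.items()},
                categorical={v: dict(d[gname]) for v, d in _CATEGORICAL_DEFAULTS.items()},
                continuous={v: d[gname] for v, d in _CONTINUOUS_DEFAULTS.items()},
                icd_positive=1.0 if gname == "ALL_ICD" else 0.0,
            )
        )
    return CohortPlan(tuple(groups), seed=seed)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, n: int
) -> np.ndarray:
    """Normal(mean, sd) truncated below at 0, drawn by rejection."""
    if sd == 0:
        return np.full(n, max(mean, 0.0))
    out = rng.normal(mean, sd, size=n)
    bad = out < 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = out < 0
    return out


def generate_cohort(plan: CohortPlan) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (patients, icd_codes) frames, reproducible under the seed.

    Each group's covariates are drawn independently per patient; the
    configured ``icd_positive`` fraction of each group receives one
    qualifying OUD code (plus incidental non-qualifying codes for realism).
    """
    rng = np.random.default_rng(plan.seed)
    pat_frames, icd_rows = [], []
    offset = 0
    for spec in plan.groups:
        n = spec.n
        data: dict[str, object] = {
            "patient_id": [f"P{offset + i:06d}" for i in range(n)],
            "group": [spec.name] * n,
        }
        offset += n
        for var, levels in spec.categorical.items():
            names = list(levels)
            probs = np.array([levels[k] for k in names], dtype=float)
            probs = probs / probs.sum()
            data[var] = rng.choice(names, size=n, p=probs)
        for var, p in spec.binary.items():
            data[var] = (rng.random(n) < p).astype(int)
        for var, (mean, sd) in spec.continuous.items():
            vals = _truncated_normal(rng, mean, sd, n)
            data[var] = np.round(vals).astype(int) if var == "outpatient_encounters" else vals
        frame = pd.DataFrame(data)
        pat_frames.append(frame)

        qualifies = rng.random(n) < spec.icd_positive
        for i in range(n):
            pid = frame["patient_id"].iloc[i]
            if qualifies[i]:
                code = str(rng.choice(QUALIFYING_CODES))
                date = _STUDY_START + dt.timedelta(days=int(rng.integers(0, _STUDY_DAYS + 1)))
                icd_rows.append({"patient_id": pid, "code": code, "date": date.isoformat()})
            for _ in range(int(rng.poisson(0.5))):
                code = str(rng.choice(NON_QUALIFYING_CODES))
                date = _STUDY_START + dt.timedelta(days=int(rng.integers(0, _STUDY_DAYS + 1)))
                icd_rows.append({"patient_id": pid, "code": code, "date": date.isoformat()})
    patients = pd.concat(pat_frames, ignore_index=True)
    icd = pd.DataFrame(icd_rows, columns=["patient_id", "code", "date"])
    return patients, icd
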