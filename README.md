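# opionlp

Detection of **problematic opioid use** in free-text clinical notes, and
comparison of the patients it finds against patients carrying an opioid use
disorder (OUD) diagnosis code.

OUD is chronically under-coded: clinicians often describe abuse, overuse, or
addiction to prescribed or illicit opioids in the narrative of a note without
ever recording ICD-9-CM 304.00/304.70/305.50 or an ICD-10-CM F11.x code.
`opionlp` is for health-informatics researchers who want to (1) surface that
narrative documentation at scale and (2) ask whether the patients found only
in notes differ systematically — demographically and clinically — from the
patients who were coded.

## The method

1. **Snippet extraction.** Notes are scanned for 36 key phrases (generic and
   trade opioid names such as *oxycodone* or *duragesic*, plus concept
   phrases such as *withdrawal* or *opioid dependence*). Each occurrence
   becomes a *snippet*: the key phrase plus up to 50 words of context on
   each side. Snippets are the unit of classification.
2. **Tiered rule voting.** A library of regular expressions is organised in
   four tiers applied sequentially: *absolute positive* → *canceling* →
   *general positive* → *neutral*. The first tier with a match decides the
   label (positive for the two positive tiers, negative for the other two);
   a snippet matching no tier is passed on. This ordering is what lets an
   unambiguous problem-list entry ("opioid dependence (icd-9-cm 304.00)")
   override a same-snippet allergy mention, and lets "former opioid
   dependence" cancel a phrase that would otherwise read as positive.
3. **SVM fallback.** Snippets the rules abstain on go to a linear support
   vector machine over lexically filtered n-gram counts — unigrams that are
   letters only, bigrams whose first word is letters and second word letters
   and/or digits — plus the token position of the key phrase. Every snippet
   therefore receives a label.
4. **Patient grouping.** Patients split into three mutually exclusive
   groups: `ALL_ICD` (any qualifying OUD code), `NLP_ONLY` (≥ 1 positive
   snippet, no qualifying code), and `NO_PROBLEMATIC_USE` (neither).
5. **Cohort comparison.** Groups are compared covariate-by-covariate with
   chi-square tests, Welch *t* tests, and the **absolute standardized
   difference** (ASD):

   binary: ASD = 100·|p₁−p₂| / √[(p₁(1−p₁)+p₂(1−p₂))/2]
   continuous: ASD = 100·|m₁−m₂| / √[(s₁²+s₂²)/2]

   With cohorts of tens of thousands, p-values saturate; an ASD > 10
   percentage points is the flag for a meaningfully imbalanced covariate.

A synthetic-data module generates note corpora (with implanted positive and
negative key-phrase contexts and full ground truth) and patient/ICD tables
(Bernoulli flags, truncated-normal age and encounter counts, per-group
prevalences), so the whole pipeline is testable without any clinical data.

## Worked example

```python
import opionlp as o

lex = o.load_lexicon()            # the 36-phrase default lexicon
lib = o.load_pattern_library()    # the shipped seed rule library

note = ("assessment and plan reviewed today 5. opioid dependence 6. homeless "
        "single person continues methadone maintenance sister abuses hydrocodone "
        "per social history")
for s in o.extract_snippets(note, lex, note_id="n1", patient_id="p1"):
    d = o.classify_by_rules(s, lib)
    print(f"{s.key_phrase!r:22} at token {s.key_phrase_token_index:2d} "
          f"-> {d.label:8s} ({d.tier})")
```

prints

```
'opioid dependence'    at token  6 -> positive (absolute_positive)
'dependence'           at token  7 -> positive (absolute_positive)
'methadone'            at token 13 -> positive (absolute_positive)
'hydrocodone'          at token 17 -> positive (absolute_positive)
```

Four key-phrase positions yield four snippets. Because the note is short,
every snippet's ±50-word window contains the problem-list entry
"5. opioid dependence", an absolute-positive pattern — so tier precedence
classifies all four positive, even though "sister abuses hydrocodone" would
match a neutral (family-member) pattern on its own. On a pattern-free
snippet the rules abstain and the SVM decides.

The comparison side works directly from two-group summary statistics:

```python
print(o.round_half_away(o.asd_binary(0.93, 0.82)))                 # 34
print(o.round_half_away(o.asd_continuous(53.3, 12.2, 55.4, 16.1))) # 15
print(o.round_half_away(o.asd_binary(0.666, 0.186)))               # 111
```

A male-gender gap of 93% vs 82% is an ASD of 34; an age gap of 53.3±12.2 vs
55.4±16.1 years an ASD of 15; a 66.6% vs 18.6% prevalence gap in other drug
addictions an ASD of 111 — all far past the 10-point imbalance flag.

## Command line

`opionlp` exposes the pipeline as subcommands — `simulate`, `extract`,
`train`, `classify`, `evaluate`, `group`, `tally`, `compare` — reading and
writing JSONL/CSV and logging record counts at each stage. A minimal run:

```
opionlp simulate --out-dir run --seed 5 --n-patients 150 --implant-rate 0.6
opionlp extract  --corpus run/notes.jsonl --out run/snippets.csv
opionlp train    --annotations run/annotations.csv --model-out run/model.joblib --seed 5
opionlp classify --snippets run/snippets.csv --model run/model.joblib --out run/classified.csv
opionlp group    --patients run/patients.csv --icd run/icd.csv \
                 --classified run/classified.csv --out run/groups.csv
opionlp compare  --patients run/patients.csv --out run/comparison.csv
```

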