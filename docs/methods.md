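# Methods

This note records the modelling and numerical choices behind `opionlp`,
what the synthetic-data generator does and does not emulate, and the known
limitations. It documents how the package computes; every number shown by
the tests or `scripts/acceptance.py` is computed at run time.

## Snippet extraction

A snippet is one key-phrase occurrence plus up to 50 whitespace tokens of
context on each side. Choices:

- **Tokenization** splits on runs of whitespace and leaves punctuation
  attached, so the rule classifier sees raw clinical text ("304.00)" stays
  a single token). Notes shorter than the window are truncated, never
  padded — padding would inject artificial tokens into the SVM features.
- **Matching** is case-insensitive and ignores punctuation hugging a token,
  so "OxyCodone," matches the phrase "oxycodone". Phrase-internal
  whitespace is normalized to a single space.
- **Overlaps.** At one token position the longest phrase wins ("opioid
  dependence" suppresses "opioid" at the same start), which avoids counting
  the same span twice; matches starting at *different* positions each yield
  a snippet, so the trailing "dependence" inside "opioid dependence" still
  fires one token later. Whether a production system should count that
  trailing match is genuinely open; counting it is the consistent reading
  of "one snippet per match position" and is what the extraction oracle in
  the tests enumerates.

## Rule tiers

The four tiers encode a clinical reading order: explicit, unambiguous
documentation (problem-list entries, embedded ICD/SNOMED strings, checked
questionnaire boxes) outranks everything; explicit negations of currency
("former …", denial, remission) outrank bare concept mentions ("opioid
abuse"); mentions not about the patient's own current use (family members,
allergies, medication-direction template lines) pick up what remains.
Pattern order *within* a tier never changes a label, only which pattern is
reported, so the library is order-insensitive where it is safe to be and
order-sensitive only across tiers, where the ordering is the model.

The shipped library is a *seed*: a compact set encoding the documented
pattern families, validated against twelve reference example spans and
meant to be extended per site via the YAML format. It makes no claim to
the coverage of a mature production library (the original tool's full
expression set is not public). Patterns match the lowercased raw snippet
window, not the preprocessed token stream — template markup like `[x]` and
dose strings like `0.5 mg` would not survive preprocessing.

## SVM fallback

- **Preprocessing**: lowercase → whitespace tokenize → strip
  non-alphanumerics per token, dropping emptied tokens ("(ICD-9" → "icd9").
- **Vocabulary**: unigrams must be letters only (pure numbers carry no
  generalizable signal); bigram first words letters only, second words
  letters and/or digits (keeping e.g. ("dependence", "30400")). Selection
  is by document frequency (default min 2); vocabulary sizes are outcomes
  of the corpus, not targets, and are recorded in the model sidecar.
- **Features** are raw n-gram counts plus one scalar: the token index of
  the key phrase's first word in the *preprocessed* snippet, unscaled.
  Counts rather than tf-idf, and position on preprocessed rather than raw
  tokens, are the simplest defensible choices; both are isolated behind
  `FeatureSpec` if a user wants otherwise.
- **Classifier**: `LinearSVC` with default regularization (C = 1) and a
  fixed seed. A linear kernel is the standard choice for sparse n-gram
  text and keeps predictions a pure function of (spec, weights, input).
- **Labels**: the three-class annotation scheme (positive / suspected /
  negative) collapses before splitting — suspected counts as positive.
  Training uses a stratified 80/20 split; reported metrics come from the
  unseen 20%.
- **Class imbalance**: none applied by default.

## Cascade and grouping

Rules decide whenever any tier matches; the SVM only sees abstentions, so
coverage is total and the pipeline is deterministic given (library, model,
corpus). ICD positivity is exact-match for the three ICD-9 codes and
prefix-match for F11 (F11 alone is a category header in ICD-10-CM, so any
F11.x qualifies). The three groups partition the cohort; the NLP/ICD
overlap is the set of coded patients with ≥ 1 positive snippet, and its
size always equals (all NLP-positive) − |NLP_ONLY|. A patient's index date
is the earliest documentation by either route; same-day ties resolve to
the ICD date (arbitrary, but fixed and recorded). Document-level
positivity, where reported, is ≥ 1 positive snippet in the note, mirroring
the patient rule.

## Cohort statistics

- **ASD** uses the standard two-group standardized-difference convention:
  `100·|p1−p2|/√[(p1(1−p1)+p2(1−p2))/2]` for proportions and
  `100·|m1−m2|/√[(s1²+s2²)/2]` for means. Displayed values are rounded
  half away from zero to integer percent; the raw value is kept in the
  table. The imbalance flag is exactly `ASD > 10` on the raw value.
  Degenerate denominators (both proportions 0/1 with a gap, both SDs zero
  with unequal means) yield NaN — flagged undefined rather than raised,
  since one pathological row should not abort a table.
- **Chi-square** is Pearson's statistic without continuity correction,
  df = k−1; zero marginals are an error. **"Two-sample t"** is the
  two-sided Welch test from summary statistics — robust to the unequal
  SDs typical of encounter counts; whether a pooled-variance test was the
  original convention is unknowable from summary tables, and Welch is the
  safer default.
- Categorical variables are reported per level (each level as a binary
  indicator with its own ASD) with one 2×k chi-square p-value repeated on
  the level rows. No multiple-testing correction is applied — ASD, not
  the p-value, is the operative screen.

## Synthetic data

`generate_corpus` implants key-phrase-bearing context templates into
neutral clinical filler. Conditions:

- **Default rates**: `implant_rate = 0.043` (share of notes carrying a key
  phrase, matching a realistic corpus-wide fraction of a few percent) and
  `positive_rate = 0.214` (positive share among key-phrase snippets,
  roughly one in five). Experiments that need a dense, balanced corpus —
  e.g. the 2,000-snippet separable-corpus gate check — say so explicitly
  in their plan (`implant_rate = 1.0`, `positive_rate = 0.5`).
- **Template banks** mix rule-matched contexts (problem lists,
  medication-direction lines, family-history mentions, "former …" spans)
  with pattern-free contexts carrying only lexical cues, so both cascade
  paths are exercised. Template text is validated to contain no key phrase
  outside its `{KEY}` slot, making ground truth exact: the generator
  records, per implant, the note-level label and the precise number of
  snippets extraction will produce.
- **Implant pool**: the 31 single-word phrases. The five two-word concept
  phrases are excluded by default because the rule library classifies a
  bare occurrence of them unconditionally (general-positive tier), so
  implanting them into a negative context would make the intended label
  and the rule model disagree by construction. Pass `phrases=` to
  override.
- `generate_cohort` draws covariates independently per patient: Bernoulli
  flags and categorical levels at configured prevalences, age and
  encounter counts from a Normal truncated at 0 (rejection sampling),
  encounters rounded to integers. Default prevalences/means give the three
  analysis groups realistically distinct profiles (e.g. depression 61.8% /
  41.1% / 19.6%; age 53.3±12.2 / 55.4±16.1 / 58.8±18.7) with group sizes
  defaulting to a realistic cohort split (6,997 / 57,331 / 158,043), and
  the configured fraction of each group receives one qualifying OUD code.

What the generator does **not** emulate: real clinical language (filler is
a closed neutral vocabulary), covariate correlation structure (only
marginal prevalences are needed by the comparison), annotator noise,
template drift over years, or multiple implants per note. Passing tests
therefore demonstrate the machinery — extraction geometry, tier
precedence, separability-limited SVM behaviour, grouping arithmetic,
estimator consistency — not clinical-grade accuracy on real notes.

Two consequences worth noting. First, on the separable corpus the cascade
clears the 85% gate with margin; real corpora with annotator disagreement
(percent agreement in the high-80s is typical for this task) will not be
separable. Second, truncation at 0 shifts realized moments away from the
configured (mean, SD) wherever the configured distribution has substantial
mass below zero — negligible for age, material for encounter counts — so
parameter-recovery checks compare prevalence-driven ASDs and age, not
encounter ASDs, against their analytic values.

## Problem sizes used by the test suite

The suite generates everything it needs at run time: a 2,000-snippet
corpus for training/gate checks, 1,000 composed snippets for tier
precedence, 50,000 patients per group for ASD parameter recovery, 100
random contingency tables for the chi-square oracle. These sizes give
binomial/normal sampling error comfortably inside the stated tolerances
(at n = 50,000 a prevalence ASD has standard error well under one point).

## Known limitations

- The seed rule library is small; recall on real notes depends on
  extending it.
- Key-phrase matching is exact (no stemming, no misspelling tolerance).
- The SVM's position feature is unscaled; with very long windows it can
  dominate margins for extreme positions.
- Inter-rater agreement is simple percent agreement (kappa is provided as
  an extra); with prevalence-skewed labels percent agreement flatters.
- `assign_groups` requires note dates only for index dating, not grouping;
  a patient whose only positive snippets lack dates gets `index_date=None`.
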