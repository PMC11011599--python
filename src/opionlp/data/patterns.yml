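# Seed rule library for the tiered (sequential-voting) snippet classifier.
#
# Tiers are applied strictly in the order listed here: a snippet matched by
# an earlier tier is classified and removed before later tiers are tried.
#   absolute_positive -> positive   (unambiguous current problematic use:
#                                    problem-list entries, ICD/SNOMED strings
#                                    embedded in text, checked questionnaire
#                                    boxes, explicit clinician statements)
#   canceling         -> negative   (positive-sounding language that is not
#                                    current: "former ...", denial, remission)
#   general_positive  -> positive   (bare concept mentions such as
#                                    "opioid abuse")
#   neutral           -> negative   (mentions not about the patient's own
#                                    current use: family members, allergies,
#                                    medication-direction template lines)
#
# Patterns are Python regular expressions matched case-insensitively against
# the raw snippet text (lowercased, otherwise unmodified). This is a seed
# library meant to be extended for a local corpus, not an exhaustive one.
absolute_positive:
  - 'continues to struggle with'
  - '(?:opioid|opiate)\s+(?:dependence|abuse)\s*\(\s*(?:icd|snomed)'
  - '\d+\s*[.)]\s*(?:opioid|opiate)\s+(?:dependence|abuse)\b'
  - '\[\s*x\s*\].{0,60}\b(?:abuse|dependence|misuse)'
  - 'overuse of (?:opioid|opiate|pain)\S* medication'
  - 'admitted to abuse of'
canceling:
  - '\bformer\b.{0,30}\b(?:dependence|abuse|misuse)\b'
  - '\bdenies\b.{0,30}\b(?:abuse|misuse|dependence)\b'
  - '\bin (?:full |sustained )?remission\b'
  - '\bno (?:current )?evidence of\b.{0,30}\b(?:abuse|misuse|dependence)\b'
general_positive:
  - '\b(?:opioid|opiate)s?\s+(?:abuse|dependence)\b'
  - '\bpolysubstance\s+(?:abuse|dependence)\b'
  - '\b(?:opioid|opiate)\s+misuse\b'
neutral:
  - '\b(?:sister|brother|mother|father|husband|wife|spouse|son|daughter|cousin|uncle|aunt|friend)\s+(?:abuses?|uses?|misuses?)\b'
  - '\bfamily\s+(?:hx|history)\s+of\b'
  - '\ballerg(?:y|ies|ic)\b'
  - '\btake\s+(?:one|two|\d+)\s+(?:tablet|capsule|pill)s?\b'
  - '\bq\s*\d+\s*h\b'
  - '\bgive\s*:'
  - '\bprn\b'
  - '\b\d+(?:\.\d+)?\s*m(?:c)?gs?\b'
  - '\bcurrent medications?\s*:'
  - '\bwhen needed for pain\b'
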