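# Default key-phrase lexicon: 36 opioid-related terms that trigger snippet
# extraction. One phrase per line, optional tab-separated category
# (drug_name = generic/trade opioid name; other = concept phrase).
abstral	drug_name
actiq	drug_name
demerol	drug_name
dependence	other
dilaudid	drug_name
dolophine	drug_name
duragesic	drug_name
exalgo	drug_name
fentanyl	drug_name
fentora	drug_name
hydrocodone	drug_name
hydromorphone	drug_name
hysingla	drug_name
kadian	drug_name
lorcet	drug_name
lortab	drug_name
meperidine	drug_name
methadone	drug_name
methadose	drug_name
morphine	drug_name
norco	drug_name
opiate	other
opiate abuse	other
opioid	other
opioid dependence	other
oxaydo	drug_name
oxycodone	drug_name
oxycontin	drug_name
percocet	drug_name
polysubstance abuse	other
roxicet	drug_name
substance abuse	other
substance dependence	other
vicodin	drug_name
withdrawal	other
zohydro	drug_name
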