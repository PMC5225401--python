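# Synthetic stand-in for an ontology-derived interaction keyword list.
# A production deployment should substitute a keyword list extracted from the
# Interaction Network Ontology literature-mining branch; this file ships a
# small hand-written set of protein-interaction verbs and nouns so the
# annotation gate is usable out of the box. One term per line.
interact
interacts
interaction
interactions
interacting
bind
binds
binding
bound
associate
associates
association
complex
coprecipitate
coprecipitates
coimmunoprecipitated
dimerize
dimerization
heterodimer
homodimer
recruit
recruits
recruitment
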