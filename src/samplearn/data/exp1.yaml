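# Word-order language: four transitive verbs, three sentence structures.
# Labels: + grammatical, - ungrammatical, ? withheld (the exception cell).
# freq = presentations per participant during training (96 total).
name: exp1
family: word_order
items: [V1, V2, V3, V4]
slots: [C1, C2, C3]
cells:
  V1:
    C1: {label: "+", freq: 9}
    C2: {label: "+", freq: 9}
    C3: {label: "-", freq: 6}
  V2:
    C1: {label: "-", freq: 3}
    C2: {label: "+", freq: 18}
    C3: {label: "-", freq: 3}
  V3:
    C1: {label: "+", freq: 18}
    C2: {label: "-", freq: 3}
    C3: {label: "-", freq: 3}
  V4:
    C1: {label: "+", freq: 18}
    C2: {label: "?", freq: 0}
    C3: {label: "-", freq: 6}
exception_cell: [V4, C2]
nouns: [blergen, nagid, tombat]
lexicon: {V1: gund, V2: flern, V3: semz, V4: norg}
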