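# Extended word-order language: five verbs (two alternating), 160 trials.
name: exp2
family: word_order
items: [V1, V2, V3, V4, V5]
slots: [C1, C2, C3]
cells:
  V1:
    C1: {label: "+", freq: 12}
    C2: {label: "+", freq: 12}
    C3: {label: "-", freq: 8}
  V2:
    C1: {label: "+", freq: 12}
    C2: {label: "+", freq: 12}
    C3: {label: "-", freq: 8}
  V3:
    C1: {label: "-", freq: 4}
    C2: {label: "+", freq: 24}
    C3: {label: "-", freq: 4}
  V4:
    C1: {label: "+", freq: 24}
    C2: {label: "-", freq: 4}
    C3: {label: "-", freq: 4}
  V5:
    C1: {label: "+", freq: 24}
    C2: {label: "?", freq: 0}
    C3: {label: "-", freq: 8}
exception_cell: [V5, C2]
nouns: [blergen, nagid, tombat]
lexicon: {V1: gund, V2: glim, V3: flern, V4: semz, V5: norg}
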