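# Contraction language: four noun modifiers, two contraction positions
# (subject vs object, randomized across participants). 128 trials.
name: exp3
family: contraction
items: [M1, M2, M3, M4]
slots: [P1, P2]
cells:
  M1:
    P1: {label: "+", freq: 16}
    P2: {label: "+", freq: 16}
  M2:
    P1: {label: "-", freq: 16}
    P2: {label: "+", freq: 16}
  M3:
    P1: {label: "+", freq: 16}
    P2: {label: "-", freq: 16}
  M4:
    P1: {label: "+", freq: 32}
    P2: {label: "?", freq: 0}
exception_cell: [M4, P2]
nouns: [flugat, tombat, nagid]
lexicon: {M1: ka, M2: ku, M3: ko, M4: ke}
verb: semz
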