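# Default 12-reaction network for the hydrogenation of
# 1-phenyl-1,2-propanedione (A) to hydroxyketones (B-E) and diols (F-I).
# Edit source/target pairs to swap the declared k5/k12 convention.
species: [A, B, C, D, E, F, G, H, I]
reactions:
  - {index: 1, source: A, target: E}
  - {index: 2, source: A, target: B}
  - {index: 3, source: A, target: D}
  - {index: 4, source: A, target: C}
  - {index: 5, source: B, target: I}
  - {index: 6, source: B, target: F}
  - {index: 7, source: C, target: H}
  - {index: 8, source: E, target: I}
  - {index: 9, source: C, target: G}
  - {index: 10, source: E, target: H}
  - {index: 11, source: D, target: F}
  - {index: 12, source: D, target: G}
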