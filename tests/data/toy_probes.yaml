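ToySyn:
  probes:
    - TCCGTCGGTG
    - GGTCCGCGTG
    - CTCTTGCGCG
  max_mismatches: 1
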