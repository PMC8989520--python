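{
  "adapter_found": 30,
  "aligned": {
    "ToySyn": 30
  },
  "ambiguous": 0,
  "classified": 30,
  "discarded_short": 0,
  "n_in": 30,
  "per_retron": {
    "ToySyn": 30
  },
  "unassigned": 0
}
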