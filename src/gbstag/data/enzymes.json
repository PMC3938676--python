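{
  "ApeKI": {
    "remnants": ["CAGC", "CTGC"],
    "internal_patterns": ["GCWGC"]
  },
  "PstI-MspI": {
    "remnants": ["TGCAG"],
    "internal_patterns": ["CTGCAG", "CCGG"]
  },
  "PstI": {
    "remnants": ["TGCAG"],
    "internal_patterns": ["CTGCAG"]
  },
  "EcoT22I": {
    "remnants": ["TGCAT"],
    "internal_patterns": ["ATGCAT"]
  }
}
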