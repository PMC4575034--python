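{
  "A": {
    "donors": {"N6": 1},
    "acceptors": {"N7": 1, "N3": 1}
  },
  "C": {
    "donors": {"N4": 1},
    "acceptors": {"O2": 1}
  },
  "G": {
    "donors": {"N2": 1},
    "acceptors": {"O6": 1, "N7": 1, "N3": 1}
  },
  "T": {
    "donors": {},
    "acceptors": {"O4": 1, "O2": 2}
  }
}
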