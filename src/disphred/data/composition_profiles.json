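{
  "folded_like": {
    "description": "Globular-protein-like composition biased toward hydrophobic residues and depleted of charge; emulates single-chain folded structures.",
    "weights": {
      "I": 0.10, "L": 0.13, "V": 0.10, "F": 0.07, "A": 0.11,
      "M": 0.03, "W": 0.02, "Y": 0.04, "C": 0.02, "G": 0.07,
      "T": 0.06, "S": 0.05, "N": 0.04, "Q": 0.03, "D": 0.03,
      "E": 0.03, "K": 0.03, "R": 0.02, "H": 0.02, "P": 0.02
    }
  },
  "disordered_like": {
    "description": "IDP-like composition enriched in E, K, S, P, Q and depleted of aromatics and aliphatics; emulates fully disordered proteins.",
    "weights": {
      "E": 0.16, "K": 0.13, "S": 0.11, "P": 0.10, "Q": 0.08,
      "G": 0.09, "A": 0.08, "D": 0.07, "T": 0.05, "N": 0.04,
      "R": 0.03, "H": 0.01, "L": 0.02, "I": 0.01, "V": 0.02
    }
  }
}
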