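{
  "name": "papa_prion_propensity",
  "kind": "prion",
  "context": "Sup35",
  "citation": "Toombs JA, McCarty BR, Ross ED (2010) Compositional determinants of prion formation in yeast. Mol Cell Biol 30:319-332; per-residue prion propensity scores as distributed in the public PAPA implementation (Toombs et al. 2012).",
  "note": "External reference scale, transcribed from the published PAPA source. Input data for cross-scale comparison only; not derived by this package.",
  "values": {
    "A": -0.396490246,
    "C": 0.415164505,
    "D": -1.276997939,
    "E": -0.605023827,
    "F": 0.838732498,
    "G": -0.039220713,
    "H": -0.278573356,
    "I": 0.813697862,
    "K": -1.576748587,
    "L": -0.040005335,
    "M": 0.673729095,
    "N": 0.080295334,
    "P": -1.395433436,
    "Q": 0.069168387,
    "R": -0.405858577,
    "S": -0.219203394,
    "T": -0.213053835,
    "V": 0.813697862,
    "W": 0.666735081,
    "Y": 0.77865336
  }
}
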