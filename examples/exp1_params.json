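{
  "moral": {"C": 0.45, "P_Moral": 0.50, "P_Hypocritical": 0.30, "P_Antisocial": 0.20, "b": 0.15},
  "neutral": {"C": 0.40, "P_Moral": 0.30, "P_Hypocritical": 0.25, "P_Antisocial": 0.20, "b": 0.12}
}
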