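{
  "moral": {"C": 0.60, "P_Moral": 0.45, "P_Hypocritical": 0.35, "P_Antisocial": 0.25, "b": 0.08},
  "neutral": {"C": 0.50, "P_Moral": 0.30, "P_Hypocritical": 0.22, "P_Antisocial": 0.25, "b": 0.06}
}
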