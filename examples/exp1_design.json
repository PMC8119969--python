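{
  "n_participants": 98,
  "n_trials_per_participant": 20,
  "frac_partner_cooperate": 0.5,
  "endowment": 400,
  "punishment_cost_min": 1,
  "punishment_cost_max": 9,
  "punishment_multiplier": 10,
  "partner_punishes_unilateral_defection": false,
  "framing_arms": ["moral", "neutral"]
}
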