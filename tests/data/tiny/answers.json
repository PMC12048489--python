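{
  "description": "Hand-enumerated downstream partners (>=4 synapses from the single seed axon), read off the aggregated synapse counts of the shipped tiny tables.",
  "downstream_partners_threshold_4": {
    "t1l_claw_flex_00": ["mn_m08_00", "pm_claw_flex_m08_00", "pm_claw_flex_m09_00"],
    "t1l_hook_flex_00": ["in_9a_gate_00", "in_loc_hook_flex_00", "pm_hook_flex_m09_00"],
    "t1l_club_00": ["frag_000", "in_10b_00"],
    "t1l_club_01": ["in_10b_01"]
  }
}
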