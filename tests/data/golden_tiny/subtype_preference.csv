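neuron_id,claw_ext,claw_flex,hook_ext,hook_flex,club
frag_000,0,0,0,0.10000000000000001,0.89999999999999991
in_0a0b_00,0,0,0,0,1
in_10b_00,0,0,0,0,1
in_10b_01,0,0,0,0,1
in_8b_00,0,0,0,0,1
in_9a_00,0,0,0,0,1
in_9a_gate_00,0,0,0,1,0
in_loc_hook_flex_00,0,0,0,1,0
mn_m08_00,0,1,0,0,0
pm_claw_flex_m08_00,0,1,0,0,0
pm_claw_flex_m09_00,0,1,0,0,0
pm_hook_flex_m08_00,0,0,0,1,0
pm_hook_flex_m09_00,0,0,0,1,0
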