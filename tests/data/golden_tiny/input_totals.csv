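post_id,input_total
frag_000,10
in_0a0b_00,38
in_10b_00,30
in_10b_01,22
in_8b_00,24
in_9a_00,4
in_9a_gate_00,20
in_loc_hook_flex_00,18
mn_m08_00,60
mn_m09_00,26
mn_m13_00,34
pm_claw_flex_m08_00,22
pm_claw_flex_m09_00,30
pm_hook_flex_m08_00,4
pm_hook_flex_m09_00,52
pm_ltm_00,4
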