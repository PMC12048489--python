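partner_id,count
frag_000,10
in_10b_00,12
in_10b_01,5
in_9a_gate_00,10
in_loc_hook_flex_00,9
mn_m08_00,4
pm_claw_flex_m08_00,9
pm_claw_flex_m09_00,15
pm_hook_flex_m09_00,16
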