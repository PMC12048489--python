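seed_id,partner_id,count
t1l_claw_flex_00,mn_m08_00,4
t1l_claw_flex_00,pm_claw_flex_m08_00,9
t1l_claw_flex_00,pm_claw_flex_m09_00,15
t1l_hook_flex_00,in_9a_gate_00,10
t1l_hook_flex_00,in_loc_hook_flex_00,9
t1l_hook_flex_00,pm_hook_flex_m09_00,16
t1l_club_00,frag_000,6
t1l_club_00,in_10b_00,12
t1l_club_01,in_10b_01,5
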