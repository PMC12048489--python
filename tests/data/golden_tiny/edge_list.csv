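pre_id,post_id,count
frag_000,in_0a0b_00,18
frag_000,in_10b_00,9
frag_000,in_10b_01,11
frag_000,in_8b_00,11
frag_000,in_9a_00,2
frag_000,in_9a_gate_00,10
frag_000,mn_m08_00,19
frag_000,mn_m09_00,12
frag_000,mn_m13_00,10
frag_000,pm_claw_flex_m08_00,11
frag_000,pm_claw_flex_m09_00,5
frag_000,pm_hook_flex_m09_00,19
frag_000,pm_ltm_00,2
frag_001,in_0a0b_00,1
frag_001,in_10b_00,6
frag_001,in_8b_00,1
frag_001,in_loc_hook_flex_00,9
frag_001,mn_m08_00,11
frag_001,mn_m09_00,1
frag_001,mn_m13_00,7
frag_001,pm_claw_flex_m09_00,10
frag_001,pm_hook_flex_m08_00,2
frag_001,pm_hook_flex_m09_00,7
in_0a0b_00,in_8b_00,4
in_10b_00,in_0a0b_00,10
in_10b_01,in_0a0b_00,7
in_8b_00,in_10b_01,6
in_8b_00,pm_ltm_00,2
in_9a_00,in_10b_00,3
in_9a_00,in_8b_00,5
in_9a_gate_00,pm_claw_flex_m08_00,2
in_9a_gate_00,pm_hook_flex_m09_00,10
pm_claw_flex_m08_00,mn_m08_00,24
pm_claw_flex_m09_00,mn_m09_00,7
pm_hook_flex_m08_00,mn_m08_00,2
pm_hook_flex_m09_00,mn_m09_00,6
pm_ltm_00,mn_m13_00,17
t1l_claw_flex_00,mn_m08_00,4
t1l_claw_flex_00,pm_claw_flex_m08_00,9
t1l_claw_flex_00,pm_claw_flex_m09_00,15
t1l_club_00,frag_000,6
t1l_club_00,in_10b_00,12
t1l_club_00,in_8b_00,3
t1l_club_00,in_9a_00,2
t1l_club_01,frag_000,3
t1l_club_01,in_0a0b_00,2
t1l_club_01,in_10b_01,5
t1l_hook_flex_00,frag_000,1
t1l_hook_flex_00,in_9a_gate_00,10
t1l_hook_flex_00,in_loc_hook_flex_00,9
t1l_hook_flex_00,pm_hook_flex_m08_00,2
t1l_hook_flex_00,pm_hook_flex_m09_00,16
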