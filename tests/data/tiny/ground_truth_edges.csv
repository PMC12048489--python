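pre_id,post_id,block
t1l_claw_flex_00,pm_claw_flex_m08_00,seed_claw_flex->premotor
t1l_claw_flex_00,pm_claw_flex_m09_00,seed_claw_flex->premotor
t1l_claw_flex_00,mn_m08_00,seed_claw_flex->mn_direct
t1l_hook_flex_00,pm_hook_flex_m08_00,seed_hook_flex->premotor
t1l_hook_flex_00,pm_hook_flex_m09_00,seed_hook_flex->premotor
t1l_hook_flex_00,in_loc_hook_flex_00,seed_hook_flex->local
t1l_hook_flex_00,in_9a_gate_00,seed_hook_flex->gate
t1l_club_00,in_10b_00,club_g0->group_pool
t1l_club_00,in_8b_00,club_g0->group_pool
t1l_club_00,in_9a_00,club->9a_shared
t1l_club_01,in_10b_01,club_g1->group_pool
t1l_club_01,in_0a0b_00,club->0a0b_shared
pm_claw_flex_m08_00,mn_m08_00,premotor->mn
pm_claw_flex_m09_00,mn_m09_00,premotor->mn
pm_hook_flex_m08_00,mn_m08_00,premotor->mn
pm_hook_flex_m09_00,mn_m09_00,premotor->mn
in_9a_gate_00,pm_claw_flex_m08_00,gate->premotor
in_9a_gate_00,pm_hook_flex_m09_00,gate->premotor
pm_ltm_00,mn_m13_00,ltm_premotor->mn
in_8b_00,pm_ltm_00,8b->ltm_premotor
in_10b_00,in_0a0b_00,recur_10b->0a0b
in_10b_01,in_0a0b_00,recur_10b->0a0b
in_8b_00,in_10b_01,recur_8b->10b
in_0a0b_00,in_8b_00,recur_0a0b->8b
in_9a_00,in_10b_00,recur_9a->10b
in_9a_00,in_8b_00,recur_9a->8b
t1l_hook_flex_00,frag_000,seed->fragment
t1l_club_00,frag_000,seed->fragment
t1l_club_01,frag_000,seed->fragment
frag_000,in_0a0b_00,background
frag_001,in_0a0b_00,background
frag_000,in_10b_00,background
frag_001,in_10b_00,background
frag_000,in_10b_01,background
frag_000,in_8b_00,background
frag_001,in_8b_00,background
frag_000,in_9a_00,background
frag_000,in_9a_gate_00,background
frag_001,in_loc_hook_flex_00,background
frag_000,mn_m08_00,background
frag_001,mn_m08_00,background
frag_000,mn_m09_00,background
frag_001,mn_m09_00,background
frag_001,mn_m13_00,background
frag_000,mn_m13_00,background
frag_000,pm_claw_flex_m08_00,background
frag_001,pm_claw_flex_m09_00,background
frag_000,pm_claw_flex_m09_00,background
frag_001,pm_hook_flex_m08_00,background
frag_000,pm_hook_flex_m09_00,background
frag_001,pm_hook_flex_m09_00,background
frag_000,pm_ltm_00,background
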