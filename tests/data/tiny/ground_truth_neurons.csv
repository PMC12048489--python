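neuron_id,organ,freq_group,dedicated_subtype,dedicated_module,dedicated
t1l_claw_flex_00,feco,-1,none,-1,False
t1l_hook_flex_00,feco,-1,none,-1,False
t1l_club_00,feco,0,none,-1,False
t1l_club_01,feco,1,none,-1,False
mn_m08_00,none,-1,none,-1,False
mn_m09_00,none,-1,none,-1,False
mn_m13_00,none,-1,none,-1,False
pm_claw_flex_m08_00,none,-1,claw_flex,8,True
pm_claw_flex_m09_00,none,-1,claw_flex,9,True
pm_hook_flex_m08_00,none,-1,hook_flex,8,True
pm_hook_flex_m09_00,none,-1,hook_flex,9,True
pm_ltm_00,none,-1,none,13,True
in_10b_00,none,-1,none,-1,False
in_10b_01,none,-1,none,-1,False
in_8b_00,none,-1,none,-1,False
in_0a0b_00,none,-1,none,-1,False
in_9a_00,none,-1,none,-1,False
in_loc_claw_flex_00,none,-1,none,-1,False
in_loc_hook_flex_00,none,-1,none,-1,False
in_9a_gate_00,none,-1,none,-1,False
frag_000,none,-1,none,-1,False
frag_001,none,-1,none,-1,False
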