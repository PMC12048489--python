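neuron_id,neuron_class,subtype,hemilineage,transmitter,segment,motor_module
t1l_claw_flex_00,sensory,claw_flex,unknown,ACh,T1L,
t1l_hook_flex_00,sensory,hook_flex,unknown,ACh,T1L,
t1l_club_00,sensory,club,unknown,ACh,T1L,
t1l_club_01,sensory,club,unknown,ACh,T1L,
mn_m08_00,motor,none,unknown,Glu,T1L,8
mn_m09_00,motor,none,unknown,Glu,T1L,9
mn_m13_00,motor,none,unknown,Glu,T1L,13
pm_claw_flex_m08_00,local,none,20A/22A,ACh,T1L,
pm_claw_flex_m09_00,local,none,13B,GABA,T1L,
pm_hook_flex_m08_00,local,none,20A/22A,ACh,T1L,
pm_hook_flex_m09_00,local,none,13B,GABA,T1L,
pm_ltm_00,local,none,20A/22A,ACh,T1L,
in_10b_00,ascending,none,10B,ACh,T1L,
in_10b_01,ascending,none,10B,ACh,T1L,
in_8b_00,ascending,none,8B,ACh,T1L,
in_0a0b_00,intersegmental,none,0A/0B,GABA,T1L,
in_9a_00,local,none,9A,GABA,T1L,
in_loc_claw_flex_00,local,none,1B,GABA,T1L,
in_loc_hook_flex_00,local,none,1B,GABA,T1L,
in_9a_gate_00,local,none,9A,GABA,T1L,
frag_000,fragment,none,unknown,unknown,T1L,
frag_001,fragment,none,unknown,unknown,T1L,
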