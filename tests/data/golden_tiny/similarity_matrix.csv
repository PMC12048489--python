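seed_id,t1l_claw_flex_00,t1l_hook_flex_00,t1l_club_00,t1l_club_01
t1l_claw_flex_00,1,0,0,0
t1l_hook_flex_00,0,1,0.021368692158534413,0.024583558114579854
t1l_club_00,0,0.021368692158534413,1,0.23008949665421111
t1l_club_01,0,0.024583558114579854,0.23008949665421111,1
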