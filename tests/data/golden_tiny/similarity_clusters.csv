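seed_id,cluster,leaf_position
t1l_claw_flex_00,0,0
t1l_hook_flex_00,1,1
t1l_club_00,2,2
t1l_club_01,3,3
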