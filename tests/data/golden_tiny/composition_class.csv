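seed_id,ascending,fragment,intersegmental,local,motor
t1l_claw_flex_00,0,0,0,0.8571428571428571,0.14285714285714285
t1l_hook_flex_00,0,0.026315789473684209,0,0.97368421052631582,0
t1l_club_00,0.65217391304347827,0.2608695652173913,0,0.086956521739130432,0
t1l_club_01,0.5,0.29999999999999999,0.20000000000000001,0,0
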