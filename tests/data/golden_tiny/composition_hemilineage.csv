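seed_id,0A/0B,10B,13B,1B,20A/22A,8B,9A,unknown
t1l_claw_flex_00,0,0,0.5357142857142857,0,0.32142857142857145,0,0,0.14285714285714285
t1l_hook_flex_00,0,0,0.42105263157894735,0.23684210526315788,0.052631578947368418,0,0.26315789473684209,0.026315789473684209
t1l_club_00,0,0.52173913043478259,0,0,0,0.13043478260869565,0.086956521739130432,0.2608695652173913
t1l_club_01,0.20000000000000001,0.5,0,0,0,0,0,0.29999999999999999
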