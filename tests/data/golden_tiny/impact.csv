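seed_id,module,impact_1,impact_2,impact_3,impact_total
t1l_claw_flex_00,8,0.066666666666666666,0.16363636363636366,0,0.23030303030303034
t1l_claw_flex_00,9,0,-0.13461538461538461,0,-0.13461538461538461
t1l_claw_flex_00,13,0,0,0,0
t1l_hook_flex_00,8,0,0,0,0
t1l_hook_flex_00,9,0,-0.071005917159763315,0.022189349112426038,-0.048816568047337278
t1l_hook_flex_00,13,0,0,0,0
t1l_club_00,8,0,0,0,0
t1l_club_00,9,0,0,0,0
t1l_club_00,13,0,0,0,0
t1l_club_01,8,0,0,0,0
t1l_club_01,9,0,0,0,0
t1l_club_01,13,0,0,0,0
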