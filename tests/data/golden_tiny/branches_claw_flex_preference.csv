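post_id,branch_1,branch_2,branch_3,n_synapses
mn_m08_00,0,0.25,0.75,4
pm_claw_flex_m08_00,0.22222222222222221,0.77777777777777779,0,9
pm_claw_flex_m09_00,0.80000000000000004,0.13333333333333333,0.066666666666666666,15
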