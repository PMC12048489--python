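post_id,branch_1,branch_2,branch_3,n_synapses
frag_000,0,0,1,1
in_9a_gate_00,0.20000000000000001,0.80000000000000004,0,10
in_loc_hook_flex_00,0.77777777777777779,0.22222222222222221,0,9
pm_hook_flex_m08_00,0,0,1,2
pm_hook_flex_m09_00,0.8125,0.1875,0,16
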