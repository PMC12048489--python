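post_id,branch_1,branch_2,branch_3,n_synapses
frag_000,0.22222222222222221,0.44444444444444442,0.33333333333333331,9
in_0a0b_00,0,0,1,2
in_10b_00,0.58333333333333337,0.41666666666666669,0,12
in_10b_01,0,0,1,5
in_8b_00,0,1,0,3
in_9a_00,0,1,0,2
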