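post_id,branch
in_10b_00,1
in_10b_00,2
in_10b_00,2
in_10b_00,2
in_10b_00,1
in_10b_00,2
in_10b_00,2
in_10b_00,1
in_10b_00,1
in_10b_00,1
in_10b_00,1
in_10b_00,1
in_8b_00,2
in_8b_00,2
in_8b_00,2
in_9a_00,2
in_9a_00,2
in_10b_01,3
in_10b_01,3
in_10b_01,3
in_10b_01,3
in_10b_01,3
in_0a0b_00,3
in_0a0b_00,3
frag_000,2
frag_000,2
frag_000,1
frag_000,1
frag_000,2
frag_000,2
frag_000,3
frag_000,3
frag_000,3
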