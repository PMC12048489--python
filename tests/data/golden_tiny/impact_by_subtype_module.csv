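subtype,8,9,13
claw_flex,0.23030303030303034,-0.13461538461538461,0
club,0,0,0
hook_flex,0,-0.048816568047337278,0
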