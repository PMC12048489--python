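group,ascending,fragment,intersegmental,local,motor
claw_flex,0,0,0,0.8571428571428571,0.14285714285714285
hook_flex,0,0.026315789473684209,0,0.97368421052631582,0
club,0.60606060606060608,0.27272727272727271,0.060606060606060608,0.060606060606060608,0
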