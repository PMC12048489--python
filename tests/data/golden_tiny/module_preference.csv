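neuron_id,module_8,module_9,module_13
frag_000,0.46341463414634149,0.29268292682926828,0.24390243902439024
frag_001,0.57894736842105265,0.052631578947368418,0.36842105263157893
pm_claw_flex_m08_00,1,0,0
pm_claw_flex_m09_00,0,1,0
pm_hook_flex_m08_00,1,0,0
pm_hook_flex_m09_00,0,1,0
pm_ltm_00,0,0,1
t1l_claw_flex_00,1,0,0
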