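post_id,branch
pm_hook_flex_m08_00,3
pm_hook_flex_m08_00,3
pm_hook_flex_m09_00,2
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,2
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,2
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
pm_hook_flex_m09_00,1
in_loc_hook_flex_00,1
in_loc_hook_flex_00,2
in_loc_hook_flex_00,1
in_loc_hook_flex_00,1
in_loc_hook_flex_00,1
in_loc_hook_flex_00,1
in_loc_hook_flex_00,1
in_loc_hook_flex_00,2
in_loc_hook_flex_00,1
in_9a_gate_00,2
in_9a_gate_00,1
in_9a_gate_00,2
in_9a_gate_00,2
in_9a_gate_00,2
in_9a_gate_00,2
in_9a_gate_00,2
in_9a_gate_00,1
in_9a_gate_00,2
in_9a_gate_00,2
frag_000,3
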