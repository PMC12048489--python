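post_id,branch
pm_claw_flex_m08_00,2
pm_claw_flex_m08_00,2
pm_claw_flex_m08_00,2
pm_claw_flex_m08_00,1
pm_claw_flex_m08_00,2
pm_claw_flex_m08_00,2
pm_claw_flex_m08_00,2
pm_claw_flex_m08_00,1
pm_claw_flex_m08_00,2
pm_claw_flex_m09_00,2
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,3
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,1
pm_claw_flex_m09_00,2
mn_m08_00,3
mn_m08_00,3
mn_m08_00,2
mn_m08_00,3
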