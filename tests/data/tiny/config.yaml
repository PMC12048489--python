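distance_threshold: 0.5
in_threshold: 3
include_fragment_inputs: true
linkage: average
log_fit_form: shifted
n_branches: 3
n_clusters: null
n_resamples: 50
out_threshold: 4
pooled_inclusion: false
rng_seed: 2
saturation_target_n: 152
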