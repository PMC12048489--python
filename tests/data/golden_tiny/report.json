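{
  "config": {
    "distance_threshold": 0.5,
    "in_threshold": 3,
    "include_fragment_inputs": true,
    "linkage": "average",
    "log_fit_form": "shifted",
    "n_branches": 3,
    "n_clusters": null,
    "n_resamples": 50,
    "out_threshold": 4,
    "pooled_inclusion": false,
    "rng_seed": 2,
    "saturation_target_n": 152
  },
  "inputs": {
    "neurons.csv": "dceaca13d583e90ab0f38f56185be0513cfae51e4b201f6aeca0e0d9707c0f8b",
    "synapses.csv": "56bb260215dfdd3b2afb9169f99bbf5bbf18d02871e5ada0c03accb87dfae0f2"
  },
  "manifest": {
    "branches_claw_flex_assignment.csv": "0a9ed12236430625e22c4f0885a48de9e7e5ad0f9b893718602b784fc6f9eee8",
    "branches_claw_flex_preference.csv": "1705a180d6dfa5b392fe41ae116c7dce666d480ae4080918faacad05a7ffd461",
    "branches_club_assignment.csv": "ee67e16233c781483dd0446cbb891c39e32d4971f718a63082a842cace2ede9b",
    "branches_club_preference.csv": "657ae0284e0baaa6e73bb29bbba62a2cfc4ac8bacb3a7013daef9486ce8bae96",
    "branches_hook_flex_assignment.csv": "5bf66794cd2fa3004ac61aeebad1d76272e70e1ea4960d15a8c132bfd3d1ee6d",
    "branches_hook_flex_preference.csv": "84b09ed756ccc3d91d0279756e451bf6c7a5d6852caf26e42e949accd28d04b7",
    "composition_by_subtype.csv": "dea4df73b3e635923e3839301621bbcb5013fc47389652c8a86ae2e1649f27e5",
    "composition_class.csv": "0f8dd2612ff47c4a86f9214d8d17f2e1e994b2be5b3ab5466c6bca48c91a57cf",
    "composition_hemilineage.csv": "74a136dffb12444bf889fe07f3a7f5f678168dd4c0bd0f05c8b40d3a692a03ca",
    "edge_list.csv": "68436bbdf2567ba70353210b2436e4a22aa4624dbae772fa6f0af2d35157efbd",
    "impact.csv": "2154d54637cc0a013dbaf27f3e5995969f7e7b4866f3e0e290ce377d9ff7ec49",
    "impact_by_subtype_module.csv": "ca327daf40510814b26f6d5ee62691e448c4b7fcbc7dfe467503f31ba2b5abe6",
    "input_totals.csv": "39c923b19eb600778a61ca0b8c9db425a25aad64571cc7108fa24d4201a5a0ca",
    "module_preference.csv": "3e5ae705f41cd43ae6fa073d1fe464d8e1b6cc0751f5f6ee293bf88377decf58",
    "partners_downstream.csv": "241936397061862a021448645f97192451501b6d46ea0f2db71b185802e52cd3",
    "partners_per_seed.csv": "156c36b71f0fae40fac0ee69895b678ce9a4e9e54dfd6183b8557964cf87ec46",
    "saturation_curve.csv": "c1ad43ed87fa5dfbdc75f8920d6421610ad5c33f410848d699f9b767deae0b00",
    "saturation_fit.csv": "790a047f7b5e6cd7771f49a149a3d75b53263eebf250f9558bdaa90132f038b4",
    "similarity_clusters.csv": "d67071c8c13ed6a7284d89deec62d35f071064c608c155e63f9892dd10346b32",
    "similarity_matrix.csv": "da3d430b0b005b900d0cbb3aa1653d31af836bb8eeaa52b6bf9c84b165b0381c",
    "subtype_preference.csv": "890eae78a32d8f0f9de82050113e07bef5033e9fa2d6926d50d9ecfabfac09ba"
  },
  "stages": {
    "branches": {
      "n_synapses_per_subtype": {
        "claw_flex": 28,
        "club": 33,
        "hook_flex": 38
      }
    },
    "edges": {
      "n_autapses": 0,
      "n_edges": 52,
      "n_neurons": 22,
      "n_seeds": 4,
      "n_synapse_rows": 398
    },
    "impact": {
      "n_modules": 3,
      "n_pairs": 12
    },
    "partners": {
      "n_partners": 9,
      "n_seed_partner_pairs": 9
    },
    "saturation": {
      "extrapolated_partners": 338.2434428185776,
      "terminal_mean_partners": 9.0
    },
    "similarity": {
      "n_clusters": 4,
      "n_seeds_clustered": 4
    }
  },
  "warnings": []
}
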