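{
  "out_dir": "scratch/pipeline_demo",
  "seed": 7,
  "simulate": {
    "n_accessions": 120,
    "n_subpops": 3,
    "fst": 0.15,
    "subgenome_sizes": {"A": [2, 2e8, 60], "B": [2, 2e8, 70], "D": [2, 2e8, 35]},
    "ld_decay_bp": 5e6,
    "hemizygous_fraction": 0.2,
    "het_call_prob": 0.9,
    "missing_rate": 0.03,
    "pav_fraction": 0.3
  },
  "ld": {"n_null_pairs": 2000, "max_pairs": 4000, "min_complete": 30},
  "structure": {"n_bootstrap": 30, "n_groups": 3},
  "scan": {"n_pcs": 3},
  "core": {"g_max": 80, "yield_column": "yield_A1"}
}
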