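{
  "out_dir": "hrsurvey_demo",
  "seed": 7,
  "simulate": true,
  "proteome_fasta": null,
  "n_proteins": 40,
  "planting_rate": 0.5,
  "n_shuffles": 200,
  "matrix_name": "BLOSUM50",
  "gap_open": -10,
  "gap_extend": -2,
  "homolog_expect": 0.001,
  "seed_expect": 1e-05,
  "reference_coverage": 0.95,
  "protein_coverage": 0.85,
  "anchor_weight": 5.0,
  "hit_expect": 0.001,
  "calibration_n": 300,
  "n_categories": 6,
  "gamma_shape": 1.151,
  "collapse_support": 0.6,
  "min_orphan": 50,
  "max_tree_tips": 8,
  "sites_divergence": [0.1, 0.8]
}
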