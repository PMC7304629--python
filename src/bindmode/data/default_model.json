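{
  "feature_config": {
    "composition_statistic": "topidp",
    "disorder_source": "builtin-fallback",
    "flank_len": 20,
    "hydropathy_scale": "kyte-doolittle",
    "max_len": 9,
    "min_len": 5
  },
  "gamma": -0.35416836116198236,
  "lambda1": 1.8715895688902264,
  "lambda2": -0.9430349720323689,
  "lambda3": 0.4415510960237791,
  "provenance": {
    "date": "2026-10-01",
    "n_examples": 2000,
    "note": "NON-CANONICAL default model fitted on simulated labelled regions; train on curated regions with external disorder scores for benchmark-quality predictions",
    "simulation_seed": 20260101,
    "training": "synthetic",
    "training_set_hash": "3dc2bd187988e7fb"
  }
}
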