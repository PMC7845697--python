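{
 "description": "Published benchmark AUROC values for drug/natural-compound indication prediction across 15 diseases, plus summary literature-evidence statistics; distributed for worked examples and report-table reproduction.",
 "diseases": [
  "Carcinoma",
  "Hypertension",
  "Pain",
  "Diabetes mellitus, type 2",
  "Arthritis, rheumatoid",
  "Urinary tract infections",
  "Alzheimer's disease",
  "Bacterial infections",
  "Parkinson's disease",
  "Heart failure",
  "Sleep initiation and maintenance disorders",
  "Skin diseases",
  "Nausea",
  "Myocardial infarction",
  "Stroke"
 ],
 "auroc": {
  "partially_connected_all_features": [
   0.774,
   0.97,
   0.943,
   0.85,
   0.774,
   0.985,
   0.864,
   0.948,
   0.995,
   0.88,
   0.875,
   0.774,
   0.934,
   0.964,
   0.972
  ],
  "fully_connected_all_features": [
   0.684,
   0.962,
   0.776,
   0.765,
   0.692,
   0.983,
   0.757,
   0.926,
   0.947,
   0.873,
   0.846,
   0.789,
   0.971,
   0.798,
   0.974
  ],
  "fully_connected_latent_only": [
   0.767,
   0.955,
   0.84,
   0.824,
   0.692,
   0.948,
   0.859,
   0.88,
   0.977,
   0.865,
   0.865,
   0.759,
   0.865,
   0.8,
   0.971
  ],
  "fully_connected_interaction_only": [
   0.702,
   0.882,
   0.815,
   0.564,
   0.683,
   0.986,
   0.588,
   0.717,
   0.913,
   0.727,
   0.669,
   0.587,
   0.957,
   0.975,
   0.946
  ],
  "fully_connected_chemical_only": [
   0.711,
   0.777,
   0.611,
   0.616,
   0.667,
   0.944,
   0.81,
   0.865,
   0.953,
   0.833,
   0.87,
   0.653,
   0.798,
   0.766,
   0.949
  ],
  "logistic_regression": [
   0.673,
   0.827,
   0.761,
   0.714,
   0.653,
   0.903,
   0.772,
   0.851,
   0.91,
   0.813,
   0.751,
   0.725,
   0.812,
   0.836,
   0.915
  ],
  "svm": [
   0.715,
   0.846,
   0.793,
   0.766,
   0.688,
   0.934,
   0.817,
   0.826,
   0.952,
   0.807,
   0.796,
   0.74,
   0.912,
   0.881,
   0.964
  ],
  "xgboost": [
   0.752,
   0.878,
   0.822,
   0.81,
   0.725,
   0.952,
   0.831,
   0.916,
   0.963,
   0.833,
   0.855,
   0.781,
   0.892,
   0.893,
   0.967
  ],
  "natural_compounds_verified": [
   0.767,
   0.912,
   0.871,
   0.793,
   0.725,
   0.846,
   0.827,
   0.879,
   0.924,
   0.808,
   0.797,
   0.718,
   0.844,
   0.902,
   0.87
  ],
  "natural_compounds_verified_and_inferred": [
   0.813,
   0.935,
   0.903,
   0.822,
   0.761,
   0.91,
   0.841,
   0.927,
   0.961,
   0.894,
   0.867,
   0.785,
   0.913,
   0.947,
   0.969
  ]
 },
 "proximity_auroc": {
  "rwr": 0.776,
  "closest": 0.721,
  "shortest": 0.697,
  "kernel": 0.713,
  "center": 0.707,
  "separation": 0.71
 },
 "literature": {
  "cooccurrence_mean": {
   "high": 0.87,
   "low": 0.09,
   "random": 0.23
  },
  "cooccurrence_sd": {
   "high": 0.18,
   "low": 0.03,
   "random": 0.11
  },
  "jaccard_mean": {
   "high": 0.000107,
   "low": 2.17e-08,
   "random": 4.31e-05
  },
  "n_significant": {
   "high": 58.53,
   "low": 13.46,
   "random": 27.86
  }
 },
 "atc_cosine": {
  "same_group": [
   0.417,
   0.478,
   0.551,
   0.603,
   0.608
  ],
  "random_range": [
   0.341,
   0.369
  ]
 }
}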