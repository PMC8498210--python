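{
  "feature_names": [
    "mean_velocity_planar",
    "rms_jerk_ml",
    "rms_jerk_ap",
    "neg_loglik_per_sample",
    "transition_entropy_rate",
    "largest_state_scale"
  ],
  "feature_means": [
    27.329494647886527,
    84343.62645336545,
    120635.96056055397,
    -0.5899035292484807,
    0.41625319902521807,
    0.332191727484748
  ],
  "feature_scales": [
    15.854954481468353,
    48809.12853442608,
    69971.58754593783,
    1.0083128215968984,
    0.0876377982374947,
    0.19216369889624993
  ],
  "feature_weights": [
    1.0,
    1.0,
    1.0,
    1.0,
    1.0,
    1.0
  ],
  "decile_edges": [
    -4.87789097800956,
    -4.0409828664743985,
    -3.3823997025126196,
    -2.648623307957449,
    -1.729564220904516,
    -0.5633461857267545,
    1.1840719586821988,
    4.151032850836709,
    8.004186325163316
  ]
}
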