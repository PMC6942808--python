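{
  "mean": {"mean_score": 2.72, "variable_coefficient": 0.31, "full_mark_rate": 24.59},
  "sd": {"mean_score": 0.65, "variable_coefficient": 0.13, "full_mark_rate": 21.64},
  "threshold": {"score_min": 2.07, "cv_max": 0.44, "fullmark_min": 2.94},
  "n_experts": 54,
  "n_items": 47
}
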