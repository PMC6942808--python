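{
  "gender": {
    "row_labels": ["positive", "negative"],
    "col_labels": ["male", "female"],
    "counts": [[231, 222], [109, 98]],
    "reported_chi2": 0.157
  },
  "age_group": {
    "row_labels": ["positive", "negative"],
    "col_labels": ["3-6", "7-14"],
    "counts": [[250, 203], [66, 141]],
    "reported_chi2": 30.918
  },
  "n_total": 660,
  "n_positive": 453,
  "n_negative": 207
}
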