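{
  "lab_label": "B",
  "n_replicates": 3,
  "aggregation": "count_based",
  "min_pos_for_positive": 2,
  "inconclusive_on_exactly_one": true,
  "min_valid_crossing_h": null,
  "max_assay_h": 90.0,
  "repeat_policy": "pool_replicates"
}
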