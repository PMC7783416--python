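# Replication fixture: the design constants of the case-control study this
# package emulates.  Group sizes, demographics, the CD deficit-cell mixture
# (margins: recognition 23%, regulation 18%, learning 13%; no deficit 56.3%;
# all three 1%), and the LPE prevalence targets (CD 43.7%, TDC 18.3%) are the
# published sample values; noise_sd 0.5 is the high-separability measurement
# setting used for parameter-recovery runs.
cohort:
  n_cd: 542
  n_tdc: 710
  age_range: [9.0, 19.0]
  bracket_edges: [9.0, 13.0, 16.0, 19.0]
  sex_ratio_by_group: {CD: 0.585, TDC: 0.675}
  iq_mean_sd_by_group: {CD: [94.9, 12.4], TDC: [103.5, 12.2]}
  ses_mean_sd_by_group: {CD: [-0.29, 0.93], TDC: [0.28, 1.03]}
  # cell order: none, REC, LRN, REG, REC+LRN, REC+REG, LRN+REG, REC+LRN+REG
  deficit_class_probs_cd: [0.563, 0.157, 0.077, 0.110, 0.023, 0.040, 0.020, 0.010]
  deficit_class_probs_tdc: [0.729, 0.081, 0.081, 0.081, 0.009, 0.009, 0.009, 0.001]
  domain_corr:
    - [1.0, 0.3, 0.3]
    - [0.3, 1.0, 0.3]
    - [0.3, 0.3, 1.0]
  deficit_shift: 1.8
  group_shift_cd: -0.15
  noise_sd: 0.5
  seed: 1
clinical:
  lpe_target_by_group: {CD: 0.437, TDC: 0.183}
analysis:
  q: 0.10
  fit_sample: pooled
  quantile_method: linear
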