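{
  "avg_rate": 1.0,
  "ap_peak": 2.0,
  "fast_trough": 2.0,
  "slow_trough": 2.0,
  "slow_trough_t_frac": 0.05,
  "ap_width": 0.1,
  "latency": 0.005,
  "first_isi": 0.005,
  "isi_cv": 0.05,
  "mean_isi": 0.005,
  "adaptation_index": 0.02,
  "baseline_v": 1.0
}
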