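{
  "name": "SK", "ion": "k", "erev": -107.0, "q10": 2.3, "t_ref": 21.0,
  "ca_gate": {"power": 1, "ca_half": 0.00043, "hill": 4.8, "tau": 1.0}
}
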