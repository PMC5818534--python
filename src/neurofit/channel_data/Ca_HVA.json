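{
  "name": "Ca_HVA", "ion": "ca", "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 2,
     "inf": {"form": "rates",
             "alpha": {"form": "explinear", "a": 0.055, "vh": -27.0, "k": 3.8},
             "beta":  {"form": "exp", "a": 0.94, "vh": -75.0, "k": -17.0}},
     "tau": {"form": "rates",
             "alpha": {"form": "explinear", "a": 0.055, "vh": -27.0, "k": 3.8},
             "beta":  {"form": "exp", "a": 0.94, "vh": -75.0, "k": -17.0}}},
    {"name": "h", "power": 1,
     "inf": {"form": "rates",
             "alpha": {"form": "exp", "a": 0.000457, "vh": -13.0, "k": -50.0},
             "beta":  {"form": "sigmoid", "a": 0.0065, "vh": -15.0, "k": 28.0}},
     "tau": {"form": "rates",
             "alpha": {"form": "exp", "a": 0.000457, "vh": -13.0, "k": -50.0},
             "beta":  {"form": "sigmoid", "a": 0.0065, "vh": -15.0, "k": 28.0}}}
  ]
}
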