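{
  "name": "NaTs", "ion": "na", "erev": 53.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 3,
     "inf": {"form": "rates",
             "alpha": {"form": "explinear", "a": 0.182, "vh": -32.0, "k": 6.0},
             "beta":  {"form": "explinear", "a": -0.124, "vh": -32.0, "k": -6.0}},
     "tau": {"form": "rates",
             "alpha": {"form": "explinear", "a": 0.182, "vh": -32.0, "k": 6.0},
             "beta":  {"form": "explinear", "a": -0.124, "vh": -32.0, "k": -6.0}}},
    {"name": "h", "power": 1,
     "inf": {"form": "rates",
             "alpha": {"form": "explinear", "a": -0.015, "vh": -60.0, "k": -6.0},
             "beta":  {"form": "explinear", "a": 0.015, "vh": -60.0, "k": 6.0}},
     "tau": {"form": "rates",
             "alpha": {"form": "explinear", "a": -0.015, "vh": -60.0, "k": -6.0},
             "beta":  {"form": "explinear", "a": 0.015, "vh": -60.0, "k": 6.0}}}
  ]
}
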