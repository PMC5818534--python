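{
  "name": "Ih", "ion": "nonspecific", "erev": -45.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 1,
     "inf": {"form": "rates",
             "alpha": {"form": "explinear", "a": -0.00643, "vh": -154.9, "k": -11.9},
             "beta":  {"form": "exp", "a": 0.193, "vh": 0.0, "k": 33.1}},
     "tau": {"form": "rates",
             "alpha": {"form": "explinear", "a": -0.00643, "vh": -154.9, "k": -11.9},
             "beta":  {"form": "exp", "a": 0.193, "vh": 0.0, "k": 33.1}}}
  ]
}
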