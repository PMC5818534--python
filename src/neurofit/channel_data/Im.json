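{
  "name": "Im", "ion": "k", "erev": -107.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 1,
     "inf": {"form": "rates",
             "alpha": {"form": "exp", "a": 0.0033, "vh": -35.0, "k": 10.0},
             "beta":  {"form": "exp", "a": 0.0033, "vh": -35.0, "k": -10.0}},
     "tau": {"form": "rates",
             "alpha": {"form": "exp", "a": 0.0033, "vh": -35.0, "k": 10.0},
             "beta":  {"form": "exp", "a": 0.0033, "vh": -35.0, "k": -10.0}}}
  ]
}
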