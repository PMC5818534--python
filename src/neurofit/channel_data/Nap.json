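{
  "name": "Nap", "ion": "na", "erev": 53.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 3,
     "inf": {"form": "sigmoid", "vhalf": -52.6, "k": 4.6},
     "tau": {"form": "rates", "scale": 6.0,
             "alpha": {"form": "explinear", "a": 0.182, "vh": -38.0, "k": 6.0},
             "beta":  {"form": "explinear", "a": -0.124, "vh": -38.0, "k": -6.0}}},
    {"name": "h", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": -48.8, "k": -10.0},
     "tau": {"form": "rates",
             "alpha": {"form": "explinear", "a": -2.88e-6, "vh": -17.0, "k": -4.63},
             "beta":  {"form": "explinear", "a": 6.94e-6, "vh": -64.4, "k": 2.63}}}
  ]
}
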