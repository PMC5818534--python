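{
  "name": "K_T", "ion": "k", "erev": -107.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 4,
     "inf": {"form": "sigmoid", "vhalf": -10.0, "k": 19.0},
     "tau": {"form": "gauss", "base": 0.34, "amp": 0.92, "vh": -81.0, "k": 59.0}},
    {"name": "h", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": -76.0, "k": -10.0},
     "tau": {"form": "gauss", "base": 8.0, "amp": 49.0, "vh": -83.0, "k": 23.0}}
  ]
}
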