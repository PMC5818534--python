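{
  "name": "Kv2", "ion": "k", "erev": -107.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 2,
     "inf": {"form": "sigmoid", "vhalf": -9.0, "k": 11.0},
     "tau": {"form": "gauss", "base": 0.7, "amp": 15.0, "vh": -20.0, "k": 30.0}},
    {"name": "h", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": -58.0, "k": -11.0},
     "tau": {"form": "gauss", "base": 360.0, "amp": 1000.0, "vh": -75.0, "k": 48.0}}
  ]
}
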