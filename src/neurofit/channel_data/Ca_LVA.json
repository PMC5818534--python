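{
  "name": "Ca_LVA", "ion": "ca", "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 2,
     "inf": {"form": "sigmoid", "vhalf": -40.0, "k": 6.0},
     "tau": {"form": "sigmoid", "base": 5.0, "amp": 20.0, "vh": -35.0, "k": -5.0}},
    {"name": "h", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": -90.0, "k": -6.4},
     "tau": {"form": "sigmoid", "base": 20.0, "amp": 50.0, "vh": -50.0, "k": -7.0}}
  ]
}
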