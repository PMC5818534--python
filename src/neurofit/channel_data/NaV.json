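{
  "name": "NaV", "ion": "na", "erev": 53.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 3,
     "inf": {"form": "sigmoid", "vhalf": -34.0, "k": 4.5},
     "tau": {"form": "gauss", "base": 0.04, "amp": 0.10, "vh": -35.0, "k": 15.0}},
    {"name": "h", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": -46.0, "k": -7.0},
     "tau": {"form": "sigmoid", "base": 0.25, "amp": 1.2, "vh": -40.0, "k": -8.0}}
  ]
}
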