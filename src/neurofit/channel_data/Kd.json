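{
  "name": "Kd", "ion": "k", "erev": -107.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": -43.0, "k": 8.0},
     "tau": {"form": "constant", "value": 1.0}},
    {"name": "h", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": -67.0, "k": -7.3},
     "tau": {"form": "constant", "value": 1500.0}}
  ]
}
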