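{
  "name": "Kv3_1", "ion": "k", "erev": -107.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": 18.7, "k": 9.7},
     "tau": {"form": "sigmoid", "base": 0.05, "amp": 4.0, "vh": -46.56, "k": -44.14}}
  ]
}
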