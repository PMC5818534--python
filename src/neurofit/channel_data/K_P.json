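{
  "name": "K_P", "ion": "k", "erev": -107.0, "q10": 2.3, "t_ref": 21.0,
  "gates": [
    {"name": "m", "power": 2,
     "inf": {"form": "sigmoid", "vhalf": -11.0, "k": 12.0},
     "tau": {"form": "two_exp", "vsplit": -50.0, "base": 1.25,
             "amp_lo": 175.03, "b_lo": 0.026, "amp_hi": 13.0, "b_hi": -0.026}},
    {"name": "h", "power": 1,
     "inf": {"form": "sigmoid", "vhalf": -64.0, "k": -11.0},
     "tau": {"form": "gauss", "base": 360.0, "amp": 1010.0, "vh": -85.0, "k": 48.0}}
  ]
}
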