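{
  "gbar_NaTs": [0.05, 5.0],
  "gbar_NaV": [0.05, 5.0],
  "gbar_Nap": [1e-6, 1e-3],
  "gbar_K_P": [5e-3, 1.0],
  "gbar_K_T": [1e-4, 0.1],
  "gbar_Kv2": [1e-3, 1.0],
  "gbar_Kd": [1e-5, 1e-2],
  "gbar_Kv3_1": [1e-4, 3.0],
  "gbar_Im": [1e-6, 1e-2],
  "gbar_SK": [1e-5, 0.1],
  "gbar_Ca_HVA": [1e-6, 1e-3],
  "gbar_Ca_LVA": [1e-6, 1e-2],
  "gbar_Ih": [1e-6, 1e-3],
  "tau_removal": [5.0, 1000.0],
  "binding_ratio": [1.0, 10000.0],
  "g_pas": [1e-6, 1e-3]
}
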