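{
  "mu_S": 0.0957,
  "mu_M": 0.2447,
  "mu_F": 1.0730,
  "mu_P": 0.1400,
  "N": 25000,
  "M": 450,
  "L": 50,
  "active_prob": {
    "0": 0.1020,
    "0.03": 0.3034,
    "0.1": 0.6318,
    "0.3": 0.7646,
    "1": 0.8512,
    "3": 0.8812,
    "10": 0.8945,
    "30": 0.9015,
    "100": 0.8889
  }
}
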