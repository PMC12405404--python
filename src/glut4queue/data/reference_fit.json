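{
  "mu_S": 0.2617,
  "mu_M": 2.2459,
  "mu_F": 3.9483,
  "mu_P": 0.0869,
  "N": 72000,
  "M": 450,
  "L": 50,
  "active_prob": {
    "0": 0.0309,
    "0.03": 0.1123,
    "0.1": 0.2907,
    "0.3": 0.4235,
    "1": 0.6200,
    "3": 0.7700,
    "10": 0.8945,
    "30": 0.9416,
    "100": 0.9099
  }
}
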