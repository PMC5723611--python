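{
  "interior": {"S": 371, "M": 2174, "a": 1.2, "A": 67282.16},
  "edge": {"S": 332, "M": 1966, "a": 1.2, "A": 67282.16},
  "combined": {"S": 443, "M": 4140, "a": 2.4, "A": 67282.16},
  "L1": {"S": 100, "M": 5000, "a": 15, "A": 30},
  "L2": {"S": 50, "M": 2000, "a": 1, "A": 30},
  "L3": {"S": 80, "M": 2000, "a": 2, "A": 30}
}
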