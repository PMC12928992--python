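{
  "yellow": {"DRF": 0.1, "UQAM": 0.1},
  "blue": {"DRF": 0.15, "UQAM": 0.15},
  "orange": {"DRF": 1.5, "UQAM": 1.65}
}
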