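{
  "total": 1198,
  "rejected": 37,
  "by_lab": {"DRF": 757, "UQAM": 441},
  "rejected_causes": {
    "UQAM_downstream_sensor_calibration": 5,
    "DRF_hydraulic_circuit_leak": 17,
    "DRF_stopcock_bubble_or_major_leak": 15
  }
}
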