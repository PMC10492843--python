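{
  "a0": 0.4705,
  "a1": -0.0073,
  "a2": -0.0039,
  "a3": 0.1104,
  "provenance": "published",
  "note": "Clinical-device coefficient set mapping RGB co-minus-cross differentials to the scattering-power scale."
}
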