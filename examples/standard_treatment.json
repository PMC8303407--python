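{
  "K": 200,
  "T": 240,
  "eps": 0.667,
  "Vex0": 14400,
  "Vin0": 21600,
  "Cs": 80,
  "omega_f": 20,
  "omega_pl": null,
  "Ah": 500,
  "S": 4.0
}
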