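{
  "experiment": 1,
  "seed": 20,
  "outdir": "runs/exp1",
  "canvas_width": 1200,
  "canvas_height": 600,
  "n_leaves": 1800,
  "population_n": 10000,
  "target_length_px": 120,
  "n_stimuli": 1,
  "observer_effects": {
    "both_w16_o40": 0.30,
    "both_w16_o20": 0.20,
    "both_w8_o40": 0.15,
    "both_w8_o20": 0.10
  }
}
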