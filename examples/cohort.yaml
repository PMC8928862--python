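# Small synthetic two-group cohort: 3 + 3 subjects on a reduced 32 x 48
# slice grid (the full-size default is 96 x 128, ~40 s of fitting per
# subject on one CPU).  All omitted keys keep the package defaults, which
# reproduce the reference acquisition and fat model.
phantom:
  shape: [32, 48]
  body_semiaxes: [13.0, 19.0]
  sat_thickness: 5.0
  fascia_offset: 2.5
  visceral_radius: 5.0
  visceral_offset: [-1.0, 0.0]
  spine_halfwidth: 3.0
  spine_height: 4.0
  snr: 50.0
cohort:
  n_a: 3
  n_b: 3
seed: 1
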