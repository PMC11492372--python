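analyte:
  name: ceria_oxidized
  radius_nm: 1.27
  valence: 112
  use_stokes: true
  water_layer_nm: 0.14
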