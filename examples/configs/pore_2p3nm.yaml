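pore:
  radius_nm: 2.3
  length_nm: 55
  metal_length_nm: 5
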