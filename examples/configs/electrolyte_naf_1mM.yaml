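electrolyte:
  temperature_K: 298
  species:
    - {name: Na+, concentration_M: 1.0e-3}
    - {name: F-,  concentration_M: 1.0e-3}
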