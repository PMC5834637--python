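# Synthetic two-class scene configuration: per-band mean reflectances for
# guano-stained vs background substrate, and the additive per-band offsets
# of the second "sensor" relative to the reference.
spectra:
  guano:
    green: 0.18
    red: 0.22
    nir: 0.30
  non_guano:
    green: 0.08
    red: 0.09
    nir: 0.12
sensor_offsets:
  green: 0.02
  red: -0.015
  nir: 0.03
noise_sd: 0.01
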