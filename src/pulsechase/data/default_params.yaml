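# Packaged default conveyor-belt parameter sets (days; fractions).
# These are the values behind pulsechase.conveyor.default_parameters().
eosinophil:
  cell_type: eosinophil
  delay_shift: 3.6
  delay_mean_extra: 3.0
  blood_half_life: 2.5
  airway_influx_fraction: 0.1
  airway_residence_mean: 5.0
  airway_pool_relative: 10.0
  production_scale: 1.0
basophil:
  cell_type: basophil
  delay_shift: 5.6
  delay_mean_extra: 3.5
  blood_half_life: 3.5
  airway_influx_fraction: 0.1
  airway_residence_mean: 5.0
  airway_pool_relative: 10.0
  production_scale: 1.0
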