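# Stage-structured population on a seasonally flooded river mask.
domain: {width: 20, height: 20}
river: {width: 1.5, value: 16.0}
stage:
  k_rain_amplitude: 8.0
  k_rain_period: 365.0
  larval_classes: 10
  adult_survival: 0.875
  eggs_per_female: 10.0
  sigma_move: 0.5
  max_mating_distance: 1.0
  dispersal_radius: 2.0
n0_adults: 300
ticks: 400
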