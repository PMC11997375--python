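# Two sexes, females choose a male within the mating kernel; offspring are
# produced by females only.  Used for sex-specific spatial structure.
bounds: {x_min: 0, x_max: 25, y_min: 0, y_max: 25, boundary: reprising}
K: 5.0
ticks: 250
seed: 7
dioecious: true
kernels:
  interaction: {family: gaussian, scale: 1.0}
  dispersal: {family: gaussian, scale: 0.5}
  mating: {family: gaussian, scale: 1.0}
regulation: {family: bh_mortality, f: 1.0, a: 1.0}
snapshot_every: 50
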