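# Homogeneous baseline: Beverton-Holt mortality regulation (a = f = 1) on a
# flat 25 x 25 landscape; equilibrium census ~ K * area = 3125.
bounds: {x_min: 0, x_max: 25, y_min: 0, y_max: 25, boundary: reprising}
K: 5.0
ticks: 300
seed: 42
kernels:
  interaction: {family: gaussian, scale: 1.0}
  dispersal: {family: gaussian, scale: 1.0}
  mating: {family: gaussian, scale: 1.0}
regulation: {family: bh_mortality, f: 1.0, a: 1.0}
snapshot_every: 100
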