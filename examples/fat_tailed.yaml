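# Fat-tailed (t cross-section, df = 3) dispersal: rare long-range moves
# reduce clumping relative to gaussian dispersal at the same scale.
bounds: {x_min: 0, x_max: 20, y_min: 0, y_max: 20, boundary: reprising}
K: 8.0
ticks: 200
seed: 11
kernels:
  interaction: {family: gaussian, scale: 0.3}
  dispersal: {family: t, scale: 0.3, df: 3.0}
  mating: {family: gaussian, scale: 0.5}
regulation: {family: bh_mortality, f: 1.0, a: 1.0}
snapshot_every: 50
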