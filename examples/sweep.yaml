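# Selective sweep: a beneficial allele (s = 0.25 per tick, additive) starts
# at 1% frequency; selection acts on fecundity.
bounds: {x_min: 0, x_max: 15, y_min: 0, y_max: 15, boundary: reprising}
K: 5.0
ticks: 400
seed: 3
kernels:
  interaction: {family: gaussian, scale: 1.0}
  dispersal: {family: gaussian, scale: 1.0}
  mating: {family: gaussian, scale: 1.0}
regulation: {family: bh_mortality, f: 1.0, a: 1.0}
selection: {mode: fecundity, s: 0.25, h: 0.5, mu_neutral: 0.001}
n_loci: 9
initial_allele_freq: 0.01
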