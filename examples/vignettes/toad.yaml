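# Range expansion with precipitation-dependent survival and fat-tailed
# dispersal (t cross-section, df = 3).
domain: {width: 40, height: 20}
precipitation: {lo: -3.0, hi: 3.0, axis: y}
alpha_t: 0.0
beta_t: 1.0
K: 5.0
sigma: 1.0
dispersal_family: t
df: 3.0
n_intro: 100
ticks: 50
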