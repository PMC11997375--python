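# Resource-explicit regulation: discrete patches each feed a fixed number
# of individuals per tick, split equally among nearby consumers.
domain: {width: 20, height: 20}
patches: {count: 30, inds_fed_per_patch: 5.0, radius: 1.5, check_age: 2}
fecundity: 1.5
n0: 150
ticks: 120
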