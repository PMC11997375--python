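# Alpine range shift under warming: conical elevation map, affine lapse
# temperature, AR(1) interannual fluctuation, 0.016 degC/yr trend.
domain: {width: 20, height: 20}
elevation: {peak: 30.0, rows: 32, cols: 32}
climate: {T0: 30.0, lapse: 1.0, p_fluct: 0.5, s_fluct: 1.0, s_seas: 4.0, trend: 0.016}
K: 5.0
f: 1.0
sigma: 1.0
ticks: 150
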