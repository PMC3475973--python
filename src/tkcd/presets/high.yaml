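# High-toxicity scenario: constant influx of 34 toxic particles per time
# unit on the reference demography. Expect massive (~65 %) cell loss, a
# sharp body-burden peak followed by decline, with the absorption
# probability approaching (but not exceeding) one at equilibrium.
b: 10.0
d: [0.1, 0.11, 0.2, 0.9, 1.0]
delta_c: 34.0
horizon: 400.0
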