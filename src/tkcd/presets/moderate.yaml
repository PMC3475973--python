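# Moderate-toxicity scenario: constant influx of 9 toxic particles per time
# unit on the reference demography. Expect ~16 % cell loss at equilibrium
# and a body-burden peak around t ~ 15-18 followed by a slight decline.
b: 10.0
d: [0.1, 0.11, 0.2, 0.9, 1.0]
delta_c: 9.0
horizon: 400.0
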