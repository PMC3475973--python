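# Low-toxicity scenario: constant influx of 1 toxic particle per time unit.
# Reference demography: b = 10 new cells per time unit, five contamination
# classes, baseline intestine of 100 cells. Expect only minor cell loss and
# a low body-burden plateau.
b: 10.0
d: [0.1, 0.11, 0.2, 0.9, 1.0]
delta_c: 1.0
horizon: 400.0
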