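# tkcd — toxicokinetics through gut-epithelium cell demography

`tkcd` simulates the uptake and elimination of a toxicant (typically a
metal) by a terrestrial invertebrate, modelling the intestine as a
population of epithelial cells rather than as a well-mixed compartment.
It is aimed at ecotoxicologists who find that the classic one-compartment
model — exponential rise to a plateau under constant exposure — cannot
reproduce the rise-then-fall body-burden trajectories reported for
beetles and other invertebrates on metal-contaminated food.

## The model

Cells are divided into contamination classes: a cell in class
*i* ∈ {1, …, *l*} carries *i* − 1 toxic particles. Per unit time, *b*
fresh cells enter class 1, a cell in class *i* dies with hazard
*d*ᵢ (strictly increasing, *d*₁ > 0, *d*ₗ = 1), and a surviving cell
absorbs one of the Δ_C incoming particles with probability Δ_C/*N*,
where *N* = Σᵢ *N*ᵢ is the intestine size. The occupancies evolve as

```
Ṅ₁ = b − (d₁ + (1 − d₁) Δ_C/N) N₁
Ṅᵢ = (1 − dᵢ₋₁) (Δ_C/N) Nᵢ₋₁ − (dᵢ + (1 − dᵢ) Δ_C/N) Nᵢ      (1 < i < l)
Ṅₗ = (1 − dₗ₋₁) (Δ_C/N) Nₗ₋₁ − Nₗ
```

The body burden is C_int = Σᵢ *N*ᵢ (*i* − 1), and the instantaneous
elimination rate emerges from the class structure:

```
k = Σᵢ Nᵢ dᵢ (i − 1) / Σᵢ Nᵢ (i − 1)
```

a weighted mean of *d*₂ … *d*ₗ that depends only on the class fractions,
not on intestine size. Because heavily contaminated cells die faster,
high exposure kills cells, shrinks the gut, raises the per-cell
absorption probability's denominator pressure and the effective
elimination rate — producing the overshoot-and-decline burden kinetics
that the constant-rate linear model cannot. The classic model
Ċ_int = k_a C_ext − k_e C_int (and its phenomenological phase-switch
variants) is included for comparison; it is the degenerate single
contaminated-class case, where *k* collapses to a constant.

See `docs/methods.md` for assumptions, parameters, numerics and
limitations.

## Worked example

Run the built-in moderate-toxicity scenario (constant influx Δ_C = 9 on
the reference demography *b* = 10, *d* = (0.1, 0.11, 0.2, 0.9, 1),
starting from the clean 100-cell gut):

```python
import tkcd

traj = tkcd.run_preset("moderate")
t_peak, c_peak = traj.peak_toxicant()
final = traj.to_frame().iloc[-1]
print(f"peak C_int:  {c_peak:.2f} at t = {t_peak:.2f}")
print(f"final cells: {final['N_total']:.2f} (loss {final['loss_pct']:.1f} %)")
print(f"final k:     {final['k']:.4f}")

eq = tkcd.solve_equilibrium(tkcd.ModelParams(10, [0.1, 0.11, 0.2, 0.9, 1.0]), 9.0)
print(f"fixed point: N* = {eq.total:.2f}, C_int = {eq.c_int:.2f}")
```

prints

```
peak C_int:  43.77 at t = 18.19
final cells: 83.44 (loss 16.6 %)
final k:     0.1874
fixed point: N* = 83.44, C_int = 42.26
```

The burden peaks near 44 particles around *t* ≈ 18 time units, then
settles slightly lower; about 17 % of the epithelium is lost at
equilibrium, and the equilibrated trajectory agrees with the directly
solved stationary state. The elimination rate has risen from its onset
value *d*₂ = 0.11 to 0.187 — elimination speeds up as the class mix
shifts toward heavily contaminated cells.

The same runs are available from the shell:

```
tkcd preset --name high --out high.csv --plot high.png
tkcd simulate --config run.yaml --out traj.csv
tkcd equilibrium --delta-c-grid 0:34:1 --out equilibria.csv
tkcd classic --config classic.yaml --out classic.csv
```

Each run writes a trajectory CSV (columns `t, N_1..N_l, N_total, C_int,
loss_pct, k, q_1..q_l, delta_c`; `k` is blank while the gut is clean) and
a JSON metadata sidecar echoing the fully materialised configuration, so
any run can be reproduced exactly from its outputs.

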