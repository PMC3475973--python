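# Methods

## Model

The intestine is reduced to a single population of epithelial cells of
one type. Cells are partitioned into `l` contamination classes; a cell
in class `i` carries `i − 1` toxic particles. Three processes act per
unit time:

- **production** — `b` uncontaminated cells enter class 1;
- **death** — a cell in class `i` dies with hazard `d_i`, taking its
  particles with it (this is the only elimination route: there is no
  cell repair or decontamination);
- **absorption** — a surviving cell absorbs one of the `Δ_C` incoming
  particles with probability `Δ_C / N` (influx shared uniformly over the
  `N` cells present) and moves up one class.

The death probabilities satisfy `d_1 > 0` (baseline turnover),
`d_i < d_{i+1}` (contamination is harmful) and `d_l = 1` (the terminal
class is lethal, which forces turnover and caps the per-cell burden at
`l − 1` particles). Treating the per-step probabilities as rates gives
the ODE system stated in the README. The time-scale constant `1/Δt` is
set to 1: all reported times are in units of the underlying demographic
step, and the `d_i`, though introduced as probabilities, act as
per-unit-time hazard coefficients. This affects only the time scale,
not the qualitative dynamics.

The uncontaminated system reduces to `Ṅ_1 = b − d_1 N_1` with the unique
fixed point `N_1 = b/d_1`; every simulation starts there unless told
otherwise. A trajectory is *admissible* while `Δ_C(t)/N(t) ≤ 1` — an
absorption probability cannot exceed one. By default an inadmissible
ratio raises an error; an explicit clamp-with-warning mode exists for
exploratory use, because nothing in the model prescribes behaviour
beyond that boundary. A note on one formula: the body burden is
`C_int = Σ_i N_i (i − 1)` — the occupancy of each class weighted by its
per-cell particle count — which is the only reading consistent with the
class semantics; likewise the last link of the stationary chain below
gives `N_l`.

## Toxicity specification

The vector `d` can be given directly, or generated by sampling a
monotone mortality curve at the class centres `0 … l − 1`
(`discretize_mortality`). Built-in forms: piecewise-linear, a
saturating Hill sigmoid renormalised to reach 1 at the terminal count,
and an arbitrary user table with linear interpolation. No particular
functional form is privileged — only monotonicity and the endpoint
conditions are constrained — so the forms shipped are conveniences, not
claims. The terminal sample is pinned to exactly 1 when within `1e−6`
(configurable); a larger miss is an error rather than a silent rescale.

For substances with additive toxicity and a shared curve shape, the
influx is converted to *toxic units* by a potency factor
(`effective_influx`), keeping one `d` vector for all of them. The hybrid
case (substance-specific potency *and* curve) is the composition of the
two operations; it needs no extra machinery. The mapping from food
concentration (e.g. mg/kg) and ingestion rate to particles per time unit
is left to the user: it is substance- and species-specific and the model
has nothing to add to it.

## Exposure

`Δ_C(t)` is piecewise constant: an ordered list of `(start, level)`
segments with half-open `[start, next)` semantics (a breakpoint belongs
to the later segment) up to a horizon. Step changes suffice to express
the classic exposure-then-depuration protocol; continuous-in-time
exposure functions and feedback of gut state on feeding are out of
scope.

## Numerics

- **Integrator** — fixed-step classical RK4, `dt = 0.01` time units.
  The system is small, smooth, and non-stiff at demographically
  plausible parameters; step-halving changes the reference-scenario
  endpoints by far less than `1e−6` relative (asserted in the tests).
  An adaptive option (SciPy RK45, `rtol 1e−10 / atol 1e−12`) is
  available for unusual parameter ranges. Integration restarts exactly
  at exposure breakpoints so a step change is never straddled.
- **Equilibrium detection** — integration stops, flagged `equilibrated`,
  once `max_i |Ṅ_i| < 1e−9` within the final exposure segment; otherwise
  it runs to the horizon (default 200 time units; the built-in presets
  use 400 so that even the slowest scenario — the low-toxicity run,
  whose slowest relaxation mode is ≈ `d_1` = 0.1 — reaches the criterion
  before the horizon, at `t ≈ 207`).
- **Storage** — states are stored every step by default
  (`store_stride = 1`), plus all segment boundaries and the final state.
  Observables are computed from stored points; peak detection does not
  interpolate, so reported peak times have resolution
  `store_stride × dt`. The onset value of the elimination rate is read
  at the first stored point with positive burden, which is why
  step-resolution storage is the default.
- **Stationary states** — at constant `Δ_C`, zeroing the derivatives
  gives a forward recursion for `N_1 … N_l` in terms of the assumed size
  `N`; the solver closes the loop on `Σ_i N_i(N) = N` by damped
  fixed-point iteration (damping 0.5, start `b/d_1`, relative tolerance
  `1e−10`, at most `1e5` iterations) with Brent bracketing on
  `g(N) = Σ N_i(N) − N` as fallback. Uniqueness of the fixed point is
  assumed, not proven: the solver scans `(0, b/d_1]` on a 512-point grid
  and refuses to choose if `g` brackets more than one root. The result
  must satisfy `max|Ṅ_i| < 1e−8` when substituted into the ODEs and is
  rejected as inadmissible if `Δ_C/N* > 1`.
- **Degenerate inputs** — `b = 0` gives an empty-gut initial state and
  is rejected by the stationary solver; an exhausted gut (`N = 0`) under
  positive influx is an error. RK4 can undershoot an empty class by
  roundoff; negative occupancies within `−1e−9` are clipped to zero,
  anything larger aborts with a step-size hint. The elimination rate at
  zero burden is *undefined* (Python `None` / CSV blank / NaN in
  series), never zero.

## Observables

Per stored point: intestine size `N`, body burden `C_int`, percent cell
loss relative to the `b/d_1` baseline, class fractions `q_i = N_i/N`,
and the elimination rate `k = Σ N_i d_i (i−1) / Σ N_i (i−1)`. `k` is
identically the removal amount over the burden, is invariant under
scaling all occupancies, and is bounded by `d_2` and 1; when
contamination starts from a clean gut it starts at `d_2` (all burden in
class 2) and rises as the mix shifts upward. These identities are
asserted as property tests.

## Classic comparison models

The linear one-compartment model is evaluated in closed form
(`C(t) = (k_a/k_e) C_ext (1 − e^{−k_e t}) + C_0 e^{−k_e t}`, linear
accumulation when `k_e = 0`). Phase-switch variants swap absorption
and/or elimination constants once — triggered either at a set time or
when the internal amount first crosses a threshold (both conventions
appear in the literature; the configuration must name which) — and drop
`C_ext` to zero at a depuration start; pieces are chained continuously.
If depuration begins before the trigger is reached, the constants never
switch. A least-squares fit of the one-compartment form to a trajectory
is provided strictly as a descriptive overlay: fitting effective
constants to mechanistic output says nothing about the underlying
demographic parameters, and the package deliberately offers no fitting
of those.

## Reference scenarios and what the tests show

The three presets run the demography `b = 10`,
`d = (0.1, 0.11, 0.2, 0.9, 1)` from the 100-cell clean gut at constant
influx 1, 9 and 34. They are the package's study conditions, not tuned
quantities. Outcomes (computed, not assumed): low — burden plateau
≈ 7.6, loss ≈ 1 %; moderate — peak ≈ 43.8 at `t ≈ 18`, equilibrium loss
≈ 16.6 %; high — peak ≈ 84.8 at `t ≈ 6` followed by decline to ≈ 46.8
(roughly the moderate equilibrium level), loss ≈ 65.9 %, with
`Δ_C/N* ≈ 0.996` — admissible, but close enough to the boundary that
slightly higher influx has no admissible stationary state (the solver
then raises).

These scenarios are synthetic by construction: the death probabilities
are illustrative, chosen to span baseline turnover to lethality over
five classes. Passing tests show the implementation solves the stated
system correctly and reproduces its qualitative regimes; they do not
validate the biology — real epithelia have repair, damage-responsive
proliferation, nonuniform exposure along the gut, and whole-organism
feedbacks, all outside this model. The acceptance script's problem
sizes (horizon 400, `dt = 0.01`, five classes) are the package
defaults; the whole run takes seconds.

## Known limitations

- Constant birth rate `b`: no damage-induced compensatory proliferation.
- Deterministic mean-field ODEs only; no stochastic per-cell simulation.
- Single organ; no transport between tissues or whole-body kinetics.
- Elimination is solely by cell death; dissolved-phase efflux, granule
  retention and repair are not represented.
- Behaviour at `Δ_C/N > 1` is undefined by the model; the clamp mode is
  a pragmatic device, not a mechanism.
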