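# Methods

## The model

`clonecomp` analyses the eco-evolutionary dynamics of two competing tumor
subclones grown in co-culture: a "winner" line W (4T07) that comes to
dominate numerically, and a "loser" line L (168FARN) whose presence
nevertheless boosts the winner's growth. Population sizes are dimensionless,
relative to the total seeded population (so L + W = 1 at t = 0), and time is
in hours.

The dynamics are piecewise:

* **Phase 1** (0–`t1`, default 45 h): pure exponential growth,
  `dL/dt = r_L1 L`, `dW/dt = r_W1 W`. This is a transition period before the
  cells remodel their shared environment; empirically the loser grows faster
  here (`r_L1 > r_W1`).
* **Phase 2** (`t1`–`t2`, default 45–72 h): density-dependent competitive
  Lotka–Volterra dynamics,

      dL/dt = L (r_L2 + a L + b W),     dW/dt = W (r_W2 + c L + d W),

  with intrinsic rates `r_L2, r_W2` and interaction coefficients `a, b, c, d`
  (per normalized population unit per hour). The homotypic special cases
  (`W = 0` or `L = 0`) are logistic with carrying capacities
  `K_L = −r_L2/a` and `K_W = −r_W2/d`.
* **Phase 3** (`t2`–`t_end`, default 72–96 h): identical to phase 2 except
  the winner's intrinsic rate drops to `r_W3`, a parsimonious description of
  starvation/waste-accumulation effects late in a round. No `r_L3` exists:
  homotypic loser simulations simply extend the phase-2 model.

Phase 1 is solved in closed form; phases 2–3 use an adaptive stiff-capable
integrator (LSODA, rtol 1e−8, atol 1e−10) with hard restarts at the
boundaries, because the right-hand side is piecewise-defined. Phase
membership uses the half-open convention `[0, t1)`, `[t1, t2)`,
`[t2, t_end]`.

Two derived notions recur throughout. The **net growth rate** of a type is
its actual per-capita rate of change (intrinsic rate plus interaction
terms); its **mean** over a window is computed from log endpoints,
`(ln X(t_b) − ln X(t_a))/(t_b − t_a)`, which is mathematically identical to
time-averaging the instantaneous per-capita rate and mirrors how endpoint
assay data are used. The **gain function** is the difference
`mean g_W − mean g_L` as a function of the winner's frequency; it equals the
mean slope of the logit-transformed winner proportion
`s = logit(w) = ln(W/L)`, whose phase-2 derivative expands to

    ds/dt = r_W2 − r_L2 + (d − b) W + (c − a) L.

## Inference procedure

The pipeline (`SubcloneCompetitionModel.fit()`) recovers all nine parameters
from three data sets:

1. **Normalization.** Each time-lapse curve is fitted with a straight line
   in log space per phase segment and divided by the fitted value at 24 h,
   making curves comparable regardless of absolute fluorescence scale.
2. **Homotypic fit** (`r_L1, r_W1, r_L2, r_W2, a, d`). Per type, the
   combined exponential-plus-logistic curve — fully closed-form, with the
   phase-2 initial condition tied to the phase-1 value at `t1` — is fitted
   to the log-normalized signal of phases 1–2 jointly by trust-region least
   squares, three starts with seeded jitter to guard against local minima.
   Residuals are on the log scale (multiplicative observation error).
   Asymptotic standard errors come from the Jacobian at the optimum.
3. **Gain points.** Each 72-h assay round contributes one point: the gain
   `(s(t2) − s(t1))/(t2 − t1)` against the proportion at `t1`. Because
   assays only measure seeding and harvest proportions, the seeding logit is
   shifted by `t1 (r_W1 − r_L1)` to adjust for phase-1 exponential growth.
   (The adjustment uses the *phase-1* rates; an option substitutes the
   phase-2 rates for comparison with the alternative convention.) First-round
   points are excluded from the regression by default — in serial designs
   the initial seeding is the least reliable measurement — but their values
   are computed identically, so toggling the exclusion changes only
   membership, never values. Measured proportions of exactly 0 or 1 are
   skipped with a warning rather than clamped, which would bias the logit.
4. **Regression and limits.** Unweighted OLS of gain on `w(t1)` over
   included points, extrapolated to `w(t1) = 1` and `0`. In those limits the
   ds/dt expansion drops one term, and replacing the remaining population
   size by its phase-2 time average (closed-form logistic solution seeded
   with `exp(r·t1)`, averaged by adaptive quadrature) gives

       b = d − (gain₁ − r_W2 + r_L2) / mean(W),
       c = a + (gain₀ − r_W2 + r_L2) / mean(L).

   The sign difference between the two formulas follows from the expansion
   terms `(d − b)W` and `(c − a)L`: the gain is winner-minus-loser in both
   limits. The straight-line extrapolation is approximate by construction —
   the true gain function is mildly convex in `w(t1)`, which costs ~3%
   accuracy at the `w → 1` limit and ~10% at `w → 0` on the default seeding
   grid; propagated through the algebra this keeps `b` within a few percent
   and `|c|` below 0.001 on noiseless data.
5. **Phase-3 rate.** With everything else fixed, `r_W3` is the scalar
   minimizing squared differences between observed and model-predicted
   whole-round logit changes of 96-h assays (the fitting objective is a
   design choice; whole-round `Δs` uses exactly what the assay measures).
   States at `t2` are precomputed per record since phases 1–2 do not involve
   `r_W3`.

A separate diagnostic (`estimate_net_growth_from_curve`) estimates net
growth rates non-parametrically as centred difference quotients (5-h span)
of running-median-smoothed (5-h span) log curves, for validating the model
against time-lapse data not used in fitting.

## Synthetic data

The generator produces exactly the data structures the pipeline consumes,
with the statistical structure the inference assumes:

* trajectories seeded at total normalized size 1, observed through a
  positive fluorescence proxy with **lognormal** (multiplicative) noise of
  log-SD `intensity_sd` (default 0.05) at 45-min frames;
* flow-cytometry proportions as **binomial** counts out of `cytometry_n`
  events (default 10,000; `None` is the exact sentinel), with round-1
  dispersion inflatable by `first_round_inflation` (default 3, implemented
  as an effective-count reduction) to emulate the extra variability of the
  initial seeding;
* serial replating that resets the total size to exactly 1 while preserving
  the true composition, over a default seeding grid
  {0.05, 0.1, 0.25, 0.5, 0.75, 0.9, 0.95} for 3 rounds of 72 h (or 96 h).

It does not emulate spatial structure, cell-cycle or apoptosis readouts,
image pixels, or the paracrine metabolite concentrations themselves
(β-hydroxybutyrate, lactate, pH): interactions enter only through the
Lotka–Volterra coefficients. Passing recovery tests on these data therefore
validates the *algebra and implementation* of the pipeline — generator,
model and inference are internally consistent — not the adequacy of the
model for any particular real co-culture.

## Game-theory layer

In vivo, where resources are replenished, a frequency-dependent description
is more natural. The payoff matrix (rows: focal strategy L then W) is
`((β_L−γ, α_L−γ), (β_W−δ, α_W−δ))` with harms `α` (< 0) from the winner,
benefits `β` (> 0) from the loser, growth-rate gap `γ` (> 0) and
resource-poor penalty `δ` (≥ 0). Classification reduces to two stability
comparisons: W resists invasion iff `α_W−δ > α_L−γ`, L resists iff
`β_L−γ > β_W−δ`. This yields the winner-ESS prisoner's dilemma (the regime
the in-vitro estimates support), the loser-ESS prisoner's dilemma, the
hawk–dove game with an interior mixed ESS — and, though not part of the
narrative taxonomy, a bistable coordination regime when *both* comparisons
hold, which sign-valid matrices can produce; the classifier names it
`BISTABLE` so that every matrix gets exactly one label. Equalities within a
configurable tolerance (default 1e−12) are `BOUNDARY`.

For the mixed ESS two candidate proportions are reported and never
averaged: the published closed form `(α_W−δ−α_L+γ)/(α_W−α_L+β_L−β_W)` and
the equal-fitness root of the effective matrix. They are exact complements
(sum to 1) — an orientation ambiguity in the published expression that the
package surfaces rather than resolves. A replicator-dynamics simulator
provides a brute-force oracle for the classifier.

The numeric bridge from `a, b, c, d` to payoff entries is not identified by
the data; `heuristic_payoff_from_lv` offers a clearly-labelled illustrative
mapping (`α_L = b·K_W`, `α_W = d·K_W`, `γ = r_W2 − r_L2`, benefits supplied
by the user).

## Numerical and design choices

* **Crossover proportion.** The proportion at the start of phase 3 above
  which the loser has the higher mean phase-3 net growth rate is found by
  simulating from t = 0 across a seeding grid, evaluating the mean-rate gain
  over `[t2, t_end]` against the proportion at `t2`, and bisecting the sign
  change to 1e−4 in proportion. With the reference (printed, rounded)
  parameter set this gives 0.566. The value is very sensitive to the
  rounding of `r_W3` (printed to one significant figure): varying `r_W3`
  over [0.035, 0.045] moves the crossover across 0.45–0.69, and the
  `c = 0.000 ± 0.0005` rounding adds a comparable span. Reported values
  should be read with that sensitivity in mind.
* **Optimizer tolerances.** `least_squares` defaults (ftol/xtol 1e−8);
  bisection 1e−4; quadrature `scipy.integrate.quad` defaults; phase-3 scalar
  fit `xatol` 1e−6 on a bounded interval.
* **Degenerate inputs.** Non-finite parameters are rejected at construction;
  a positive self-interaction coefficient (no carrying capacity) is flagged
  by the homotypic fit and rejected by closed-form logistic helpers;
  zero-length mean-rate windows return instantaneous rates.
* **Determinism.** All randomness flows through `numpy.random.default_rng`
  seeds carried in `NoiseConfig` and `InferenceOptions`; identical
  configuration and seed give bitwise-identical datasets and results.

## Problem sizes

Default experiments are desk-scale: homotypic curves have 97 frames per
replicate (0–72 h at 45 min), three replicates per type; assay bundles are
7 seeding proportions × 3 replicate chains × 3 rounds (63 records) per
duration. The full noiseless generate-plus-fit cycle runs in ~3 s on one
CPU; Monte-Carlo sweeps in the test suite use 10–20 seeds.

## Known limitations

* The model is deliberately phenomenological; it declines mechanistic
  paracrine-factor equations, which would be non-identifiable without
  concentration measurements.
* The limit-extrapolation step inherits the linearity approximation
  described above; its bias is visible in `c` at the third decimal.
* `r_W3` absorbs whatever the phase-3 discrepancy is; if the true change
  were interaction-mediated (frequency-dependent), the single-rate
  adjustment would misattribute it.
* Uncertainties are reported only where the procedure defines them
  (homotypic-fit asymptotics, regression standard errors); the chained
  b/c/r_W3 estimates carry no formal intervals, matching the point-value
  character of the procedure.
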