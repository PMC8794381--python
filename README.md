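# clonecomp

Eco-evolutionary analysis of two competing tumor subclones in co-culture.

When two subclones of a tumor are grown together, their growth rates are not
independent: in the murine mammary pair modelled here, the numerically
dominant "winner" line (4T07) grows *faster* in the presence of the "loser"
line (168FARN), while the loser is suppressed — an interaction pattern
equivalent to a parasite farming its host, mediated by paracrine metabolites
rather than direct contact. `clonecomp` packages the quantitative side of
that analysis for anyone studying two competing cell populations with
time-lapse growth curves and endpoint competition assays (flow-cytometry
proportions): cancer subclones, bacterial strains, or any experimental
evolution setup with two labelled types.

## The model and the inference

Dynamics are piecewise in time, with normalized population sizes
(L + W = 1 at seeding):

* **phase 1** (0–45 h) — exponential growth: dL/dt = r_L1·L, dW/dt = r_W1·W;
* **phase 2** (45–72 h) — competitive Lotka–Volterra:
  dL/dt = L(r_L2 + aL + bW), dW/dt = W(r_W2 + cL + dW);
* **phase 3** (72–96 h) — as phase 2 with r_W2 → r_W3 (degraded environment).

The nine parameters are recovered in stages: the homotypic parameters
(r_L1, r_W1, r_L2, r_W2, a, d) by least squares on log-normalized homotypic
curves (closed-form exponential-plus-logistic model); the between-type
coefficients b and c from serial 72-h competition assays via the **gain
function** — the slope of the logit winner proportion,
ds/dt = r_W2 − r_L2 + (d−b)W + (c−a)L — regressed on the proportion at the
start of phase 2 and extrapolated to the homotypic limits w → 1 and w → 0;
and r_W3 by one-dimensional least squares on whole-round logit changes of
96-h assays. A game-theory layer classifies the interaction regime
(prisoner's dilemma vs hawk–dove, pure vs mixed ESS) from a 2×2 payoff
matrix, including a resource-poor variant.

Because no public dataset exists for the original experiments, the package
ships a synthetic-data generator that emulates the study designs
(lognormal intensity noise, binomial flow-cytometry sampling, serial
replating with dilution back to seeding density), so the entire pipeline
runs and is tested end-to-end with no external data.

## Worked example

Generate a noiseless synthetic bundle at the reference parameter set and
recover the parameters:

```python
import clonecomp as cc

params, sched = cc.REFERENCE_PARAMS, cc.PhaseSchedule()
design, noise = cc.ExperimentDesign(), cc.NoiseConfig.noiseless()

curves_L = cc.generate_homotypic_timelapse(params, sched, "L", design, noise)
curves_W = cc.generate_homotypic_timelapse(params, sched, "W", design, noise)
assays_72 = cc.generate_competition_assays(params, sched, design, noise)
assays_96 = cc.generate_competition_assays(
    params, sched, cc.ExperimentDesign(round_duration=96.0), noise)

res = cc.SubcloneCompetitionModel(curves_L, curves_W, assays_72, assays_96).fit()
print(res.summary())
```

```
Subclone competition model
==================================================================
 param    estimate     std err  interpretation
------------------------------------------------------------------
  r_L1      0.0440      0.0000  loser rate, phase 1 (/h)
  r_W1      0.0310      0.0000  winner rate, phase 1 (/h)
  r_L2      0.0730      0.0000  loser intrinsic rate, phase 2 (/h)
  r_W2      0.1020      0.0000  winner intrinsic rate, phase 2 (/h)
  r_W3      0.0458              winner intrinsic rate, phase 3 (/h)
     a     -0.0040      0.0000  effect of loser on loser
     b     -0.0098              effect of winner on loser
     c     -0.0007              effect of loser on winner
     d     -0.0080      0.0000  effect of winner on winner
   K_L     18.2500              loser carrying capacity
   K_W     12.7500              winner carrying capacity
  beta      2.4577              b/a
 gamma      0.0853              c/d
------------------------------------------------------------------
gain regression: slope -0.02337 (se 0.00067), intercept 0.06705 (se 0.00046), n=42
excluded first-round points: 21; degenerate records: 0
```

Reading the table: the loser grows faster in phase 1 (0.044 vs 0.031 /h)
but has the lower phase-2 intrinsic rate (0.073 vs 0.102 /h), offset by a
~30% higher carrying capacity (18.25 vs 12.75). The winner harms the loser
two-and-a-half times as strongly as the loser harms itself (β = b/a ≈ 2.5),
while the loser has essentially no net effect on the winner (γ = c/d ≈ 0) —
the generating values b = −0.010 and c = 0.000 are recovered through the
approximate limit-extrapolation procedure to within its design accuracy.
`res.crossover_proportion()` gives the phase-3 proportion above which the
loser outgrows the (by then self-poisoned) winner; `res.plot_gain_function()`
and `res.plot_trajectory()` visualize the fit.

The same pipeline is scriptable from the shell:

```sh
clonecomp generate --out data                 # synthetic bundle (CSV)
clonecomp fit --out fit --curves data/curves.csv \
    --assays-72h data/assays_72h.csv --assays-96h data/assays_96h.csv
clonecomp simulate --out sim                  # trajectories + logit frequencies
clonecomp classify payoff.json                # game classification
clonecomp report fit/inference.json           # parameter table + crossover
```

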