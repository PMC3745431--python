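# interpower

Power analysis for interaction (moderation) tests in ordinary-least-squares
linear regression, by Monte Carlo simulation and in closed form.

## The problem

Interaction effects — whether the association between a predictor `x1` and a
continuous outcome `y` depends on a second variable `x2` — are tested via the
product term in

```
y = β₀ + β₁·x1 + β₂·x2 + β₃·x1·x2 + e,    e ~ N(0, σ²)
```

with a t-test of H₀: β₃ = 0 on n − 4 residual degrees of freedom. Power to
detect interactions is notoriously low, and a common workaround is to elevate
the Type 1 error rate α (sometimes to 20%). This package quantifies that
tradeoff: it estimates empirical power over a grid of variable-pair kinds
(continuous×continuous, continuous×dichotomous, dichotomous×dichotomous),
sample sizes n ∈ {50, 200, 300, 500, 1000}, standardized interaction effect
sizes β₃ ∈ {0.05, 0.14, 0.26, 0.39} and error rates α ∈ {0.05, 0.10, 0.15,
0.20} — 240 scenarios — and classifies each (kind, β₃, n) triple by whether
raising α from 5% to 20% buys a *useful* gain in power (relative increase
≥ 10% and power ≥ 80% at α = 0.20).

Predictors are i.i.d. standard normal; a dichotomous predictor is a standard
normal median-split at 0 into a 0/1 indicator. Alongside the simulator, a
noncentral-t oracle gives closed-form power with noncentrality
β₃·√n·s/σ, where s ∈ {1, 0.5, 0.25} is the residualized SD of the product
column for the three pair kinds.

## Worked example

```python
from interpower import ScenarioSpec, SimulationSettings, analytic_power, estimate_power

spec = ScenarioSpec(pair_kind="cont_dich", n=200, beta3=0.39, alpha=0.05)
est = estimate_power(spec, SimulationSettings(n_reps=10_000, seed=1))
ana = analytic_power(spec)
print(f"simulated power : {est.power:.3f}  (Monte Carlo SE {est.mc_se:.4f})")
print(f"analytic power  : {ana.power:.3f}  (ncp={ana.noncentrality:.3f}, df={spec.df_resid})")
```

prints

```
simulated power : 0.768  (Monte Carlo SE 0.0042)
analytic power  : 0.784  (ncp=2.758, df=196)
```

i.e. a continuous-by-dichotomous interaction of standardized size 0.39 at
n = 200 is just short of the conventional 80% power at α = 0.05. The two
numbers differ slightly because the simulation redraws the predictors every
replicate (unconditional power) while the formula fixes the design at its
population scale; see `docs/methods.md`.

The `examples/` directory has short narrative scripts for each capability
(single-scenario power, the elevated-α tradeoff, the full-grid taxonomy).
A thin CLI mirrors the library:

```sh
interpower power --pair cd --n 200 --beta3 0.39 --alpha 0.05 --reps 10000 --seed 1
interpower analytic --pair cc --n 300 --beta3 0.14 --alpha 0.15
interpower reproduce --out-dir results/ --reps 10000 --seed 0   # full 240-cell study
```

`reproduce` writes per-cell power CSVs (simulated and analytic), the
useful-gain taxonomy, power-curve figures per pair kind, and a YAML run log
recording seed, design mode, replication count and version. Reruns with the
same config and seed are byte-identical.

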