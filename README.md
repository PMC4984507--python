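# hvhfit

Does intraspecific competition in consumer microcosms shift from
*exploitation* (indirect, via a shared resource) to *interference*
(direct obstruction of foraging) as population density rises?  `hvhfit`
implements the full analysis pipeline for answering that question in
protist–bacteria microcosm experiments: it simulates the factorial
census experiment, derives growth rates, fits the mutual-interference
functional response by maximum likelihood, and runs the GLM/AIC
model-selection layer — all on synthetic data, so every stage is
testable end to end without any external dataset.

## The model

Per-capita foraging follows the **Hassell–Varley–Holling** trophic
function,

```
f(R, C) = a R C^m / (1 + a h R C^m)
```

with attack rate *a*, handling time *h* (hours), basal resource *R*
(mg), consumer density *C* (cells/mL) and mutual-interference exponent
*m*.  Two special cases anchor the interpretation: *m* = 0 is a purely
exploitative (Holling type II) forager whose intake depends on resources
alone, and *m* = −1 is fully ratio-dependent — intake is set by resource
per consumer.  Consumer dynamics follow a MacArthur–Rosenzweig consumer
equation with conversion efficiency *e* and mortality *μ*:

```
dC/dt = C (e f(R, C) − μ)
```

From each microcosm's initial and final censuses (*N*ᵢ, *N*𝒻, Δ*t*) the
pipeline computes the intrinsic rate *r* = ln(*N*𝒻/*N*ᵢ)/Δ*t* and the
rate of change d*C*/d*t* = *r·N*ᵢ, then

1. estimates (*a*, *h*, *m*, σ) jointly across all microcosms by
   Gaussian maximum likelihood on d*C*/d*t* (with *e* = 0.8, *μ* = 0.1
   h⁻¹ held fixed),
2. holds the pooled (*a*, *h*) fixed and solves *m* for **each**
   microcosm algebraically, and
3. asks, by Gaussian GLM and AIC (ΔAIC > 2 rule), whether the
   per-microcosm *m* declines with initial density and whether resource
   availability adds explanatory power.

## Worked example

The numbered scripts under `analysis/` run the study end to end on the
default synthetic conditions (5 density × 2 resource treatments, 10
replicates, 72 h, interference shifting from −0.24 at 26 cells/mL to
−1.03 at 263 cells/mL, Poisson counting noise):

```
python analysis/01_simulate.py --seed 1
python analysis/02_growth_rates.py --seed 1
python analysis/03_fit_interference.py --seed 1
python analysis/04_interference_models.py --seed 1
python analysis/05_sensitivity.py --seed 1
```

which prints (seed 1):

```
growth records: 80 valid of 100
  C(resource_mg): F = 35.04 (df 1), p = 8.8e-08
  initial_density: F = 52.84 (df 1), p = 2.7e-10
  C(resource_mg):initial_density: F = 29.87 (df 1), p = 5.6e-07
  interaction coefficient -0.0393: subadditive (resource effect shrinks with density)
...
per-microcosm m: 54 feasible of 80; mean m at lowest/highest density: -1.01 / -1.55
m ~ density: F = 11.20 (df 1), p = 0.0015
AIC comparison: delta = 0.73 -> models indistinguishable (best: null)
```

Read: growth declines with density and the high-resource advantage is
largest at low density (negative interaction); the per-microcosm
interference exponent *m* declines significantly with density; and
adding resource level to the density-only model for *m* does not improve
it (ΔAIC ≤ 2) — competition intensifies through density-dependent
interference, not through resource-dependent exploitation.

The same stages are available as a CLI (`hvhfit simulate | fit | select
| sensitivity | all`, see `hvhfit --help`) driven by a YAML config whose
sections mirror the design, scenario, observation and fitting blocks.

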