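# Methods

## Model and assumptions

A clonal population grows for `τ` hours and is then diluted; each cell
independently survives a transfer with probability `D` (binomial
thinning — survivors can never outnumber the cells that faced the
bottleneck, unlike the Poisson with-replacement approximation).
Beneficial mutations arise only at wild-type divisions, with
probability `μ` per division and selective effects `s ~ Exp(ω)`
(growth-rate advantage `r(1+s)`); mutant-on-mutant and back mutation
are ignored, which is accurate while `μN` per cycle is small (the
multi-hit case lives in the genotype module). Mutant lineages evolve
independently of one another and of wild-type frequency (valid while
lineages are rare relative to `N`). Demographic stability ties the
growth period to the bottleneck, `D = e^{-rτ}`, except in the
resource-explicit model, where `D` and `τ` vary freely and the
population finds its own equilibrium size `N*` against the resource
supply.

Eventual-extinction probabilities come from the fixed point of the
one-cycle offspring probability generating function (pgf): geometric
growth composed with Bernoulli thinning. For the package's own model
the fixed point is the closed form `V(0,s) = (D⁻¹−1)/(D⁻⁽¹⁺ˢ⁾−1)`, and
a mutation arising mid-phase is propagated through its first bottleneck
by the corresponding first-cycle pgf. The adaptation rate `γ`
integrates the mutation supply `μNDr·e^{rt}` against `1 − V(t,s)` over
origin times and effects.

## Parameters

| name | meaning | default | note |
|------|---------|---------|------|
| `r` | max growth rate | 1 /h | `r_max = 3 /h` in the Monod model (prevents extinction at severe `D`) |
| `μ` | beneficial mutations per division | 1e-9 | rate is linear in `μ`; validation runs inflate it for statistics |
| `N` | pre-bottleneck population | 1e9 | `N* ≈ R0` in the resource model |
| `ω` | mean selective effect | 0.1 | exponential distribution |
| `D` | per-cell transfer survival | swept | `D → 1` only as analytic limit |
| `τ` | growth period | `ln(1/D)/r` or 24 h | hours |
| `k`, `R0` | Monod half-saturation, fresh-media resource | 1e9, 1e9 | one resource unit = one division |
| establishment threshold | `V(0,s)^size` cutoff | 1e-6 | exposed in every config |

## Numerical choices

- The exact rate uses nested adaptive quadrature (absolute tolerance
  1e-12, relative 1e-9); the effect integral is truncated at `40ω`
  (tail mass < 1e-10). The variant machinery instead uses fixed
  Gauss–Laguerre nodes in `s` (exact for the exponential weight) and
  Gauss–Legendre nodes in `t`; the two code paths agree to ~1e-13.
- Extinction fixed points are solved on the survival deficit
  `p = 1 − q` with `expm1`/`log1p` expressions throughout: the naive
  pgf iteration loses all precision near criticality (`D → 1`, small
  `s`), where `G(1−ε)` rounds to 1. Roots are bracketed Brent on
  `(1 − G(1−p))/p − 1` over `[1e-15, 1]`, tolerance 1e-15.
- Deterministic-growth variants treat the non-integer expected size
  `m = e^{r(1+s)(τ−t)}` as a real-valued pgf exponent
  (`(1−D+Dz)^m`, Poisson mean `Dm`), avoiding rounding artifacts.
- All optimizations over `D` run on the `ln D` scale with bounded
  scalar search; ties break toward larger `D` (the per-time binomial
  objective is flat near `D → 1`). `D → 1` results are reported as
  analytic limits, never by evaluating 0/0 forms at `D = 1`.
- The `τ`-fixed optimum `D* = 0.20319` solves `2(e^x − 1) = x·e^x`
  with `x = ln(1/D)`; a 1e5-point grid search is kept as a test oracle.

## Simulators: what they emulate, and how

**Exponential serial passage.** Growth phases are sampled *exactly*
from the Yule transition law — `n` cells for `u` hours at rate `λ`
become `n + NegBinomial(n, e^{-λu})` — so a phase is O(1) draws per
compartment at any population size, with no time-discretization error.
Mutation arrival times are drawn from the deterministic-intensity
division profile (`∝ e^{rt}`), an approximation whose error is
O(1/√N); an `exact_mode` simulates every division event per cell
(Gillespie) and the two engines are statistically indistinguishable at
small `N` in the test suite. A lineage is counted as destined to fix
("established") when its extinction bound `V(0,s)^size`, checked at
phase starts, drops below 1e-6. Mutations are generated only inside
the measurement window; cycling then continues mutation-free (cap 400
extra cycles) until every pending lineage is resolved, so `γ̂` counts
mutations *occurring* per hour that go on to fix — matching what the
theory integrates. Lineages still pending at the cap (a vanishing
minority of near-neutral effects) contribute their current survival
probability `1 − V^n` as fractional weight.

**Monod serial passage.** All replicates advance together as NumPy
arrays by Poisson tau-leaping: per-cell rate `r_max·R/(k+R)`
re-evaluated each step, one resource unit consumed per division
(exact integer mass balance per phase), adaptive step capped so
per-capita growth and relative resource drawdown stay below 5% per
step (drawdown cap carries a 0.1%-of-`k` additive slack so the
depleted tail, whose remaining divisions are negligible, can coarsen).
Transfers thin every compartment binomially and mix media
volumetrically, `R ← D·R_end + (1−D)·R0`; full replacement by `R0` is
a config switch (the two differ negligibly when the resource is
depleted at transfer). Ten burn-in cycles (mutation off) equilibrate
the population–resource balance before measurement, verified by a
stationarity check on the last burn-in cycles; `N*` is the measured
mean pre-transfer size. Establishment uses the same `V` with the
average growth rate `r̄ = ln(1/D)/τ` (the formula depends only on `D`
and `s`). Replicate extinction (e.g. `r̄` demands more growth than the
Monod maximum allows) is flagged, not raised.

**Chemostat.** No bottlenecks; per-capita washout `Φ` (binomial with
`1 − e^{-Φdt}` per step), media inflow `Φ(R0 − R)`. At balance the
Monod rate equals `Φ`, so `R_eq = kΦ/(r_max − Φ)` and
`N_eq = R0 − R_eq`, both verified against the simulator. Establishment
uses the birth–death extinction probability `1/(1+s)` — exactly the
`D → 1` limit of the serial formula, and the serial simulator at
`D = 0.9` with matched `r̄` reproduces the chemostat rate within
Monte-Carlo error.

**Genotype model.** Mutations occur at a small number of loci
(default 10, per-locus probability per division), genomes are bitmasks,
fitness is multiplicative over mutated loci, and locus effects are
quenched — drawn once per replicate from `Exp(ω)` — or fixed.
Growth uses the same exact Yule law per genotype. Because an adapting
population outgrows a fixed dilution factor once mutants dominate,
bottlenecks dilute *to the target size* (per-cell survival
`min(1, D·N/total)`), which equals plain `Bernoulli(D)` thinning while
the population is at its equilibrium and emulates the resource ceiling
of a real protocol. A locus is *fixed* at 0.99 allele frequency
(strict fixation is asymptotic; the threshold is exposed), and
*established* by the same extinction-bound rule as the lineage
simulators. With one locus and low supply the model reduces,
verifiably, to the lineage simulator; with many loci and high supply,
clonal interference makes fixations slower than the
independent-lineages prediction while `D → 1` remains optimal.

## What the generators do not emulate

Real serial-passage data add phenotypic lag, death, non-heritable
variance, multiple resources, and mutations affecting yield or lag
rather than rate; none are modelled. Passing tests show internal
consistency of theory and simulation under the stated branching-process
assumptions — not that a laboratory experiment will realize these
rates.

## Known limitations and open points

- **Closed-form accuracy.** The approximation replaces the exact
  effect average `E[s/(1+s)]` by `ω/(1+ω)`. The resulting relative
  error is ~1% at `ω = 0.01` but ~7.7% at `ω = 0.1` and ~24% (large
  `D`) to −57% (`D = 0.001`) at `ω = 1`; the test suite asserts the
  error factor itself (derivable via the exponential integral) rather
  than pretending the forms coincide. All qualitative conclusions
  (monotonicity, optima) are unaffected.
- **Effective population size.** The closed form
  `N_e = N·r·ln(D⁻¹)/(2(D⁻¹−1))` tends to `N·r/2` as `D → 1`, not `N`
  as one might expect from a constant population; the factor-2 gap is
  asserted in the tests and left as printed rather than silently
  "fixed".
- **Historical optimum.** The per-transfer deterministic/Poisson
  variant peaks at `D = e⁻²` only in the small-effect regime in which
  the earlier analyses linearized (the package reproduces this limit
  exactly as `ω → 0`); at `ω = 0.1` the full nonlinear fixed point
  shifts the optimum to `D ≈ 0.155`.
- The wild type's own demographic stochasticity is ignored in the
  default engine (exact at the phase level for growth, deterministic
  for mutation timing); `exact_mode` exists to validate this at small
  `N`.

## Problem sizes

Reduced scales are the package defaults: 150–200 replicates instead of
1,000 (a `--paper-scale` flag restores 1,000), 50-h windows for the
exponential model, 160 measured 24-h cycles per grid point for the
resource model, and Monte-Carlo oracles at 5e4–1e5 replicates. These
sizes put every statistical assertion at ≥2.5 standard errors of
separation while keeping the full suite to a few minutes on one CPU.
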