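# evopassage

Theory and stochastic simulation of how bottleneck scheduling shapes the
rate of adaptive evolution in serially passaged microbial populations —
and why continuous culture (a chemostat) maximizes it.

## The problem

Experimental evolution with bacteria alternates growth with dilution:
the culture grows for `τ` hours, then each cell survives the transfer
with probability `D` (a dilution ratio of `1/D`; the common 100:1
protocol is `D = 0.01`). Severe bottlenecks discard most newly arisen
beneficial mutations; mild bottlenecks leave little time for growth.
This package implements the branching-process theory and the simulators
needed to ask: **which `(D, τ)` schedule fixes beneficial mutations
fastest?**

The core model: a wild type grows exponentially at rate `r` (or under
Monod resource limitation `r_max·R/(k+R)`), reaching `N` cells before
each bottleneck, with `D = e^{-rτ}` for demographic stability.
Beneficial mutations arise at rate `μ` per division with effects
`s ~ Exp(ω)`. A mutant lineage born at time `t` is a Yule process, so
its pre-bottleneck size is geometric with parameter
`β = e^{-r(1+s)(τ-t)}`; the bottleneck thins it binomially. Composing
the two probability generating functions yields the eventual-extinction
probability in closed form,

    V(0,s) = (D⁻¹ − 1)/(D⁻⁽¹⁺ˢ⁾ − 1),
    V(t,s) = 1 / (1 + (1 − Dˢ)/(β(D⁻¹ − 1))),

and the adaptation rate (beneficial mutations per hour destined to fix)

    γ = (1/τ) ∫ ds (e^{−s/ω}/ω) ∫ dt μNDr·e^{rt} (1 − V(t,s))
      ≈ rμN · ω/(1+ω) · ln(D⁻¹)/(D⁻¹ − 1).

The closed form is monotone increasing in `D`: per unit time, frequent
infinitesimal bottlenecks — continuous culture — are optimal, roughly
21× faster than 100:1 passaging. If `τ` is pinned at 24 h and the
population size is set by the resource supply, the relevant factor
becomes `(ln D)²/(D⁻¹ − 1)`, maximized at `D ≈ 0.203` (~5:1). The
package also evaluates the eight combinations of modelling assumptions
used across the literature ({per-time, per-transfer} × {stochastic,
deterministic growth} × {binomial, Poisson sampling}); the historical
per-transfer/deterministic/Poisson analysis instead peaks at
`D = e⁻² ≈ 0.135` (~7.4:1), which is why earlier work recommended ~8:1.

Four simulators corroborate the theory: an exact serial-passage
simulator (Yule-law phase sampling, with a per-cell Gillespie mode for
validation), a Monod resource-explicit serial simulator, a true
chemostat with continuous inflow/outflow, and a multi-locus genotype
model exhibiting clonal interference.

## Worked example

Exact adaptation rate at a 10:1 dilution:

```
$ evopassage analytic --D 0.1 --method exact_integral
D       tau          metric    growth      sampling  gamma          method
0.1     2.302585093  per_time  stochastic  binomial  0.02162126911  exact_integral
```

0.0216 fixing mutations per hour at `N = 10⁹`, `μ = 10⁻⁹`, `r = 1/h`,
`ω = 0.1` — about one beneficial mutation destined to fix every two
days. Simulation agrees:

```
$ evopassage sweep --model exp --D-grid 0.01 0.1 0.5 --replicates 200 --t-end 50 --seed 1
model  D     tau          gamma_hat       se              gamma_theory    ...  n_established
exp    0.01  4.605170186  0.004017223958  0.0006544808784 0.004228806415  ...  37
exp    0.1   2.302585093  0.02264519858   0.001569373535  0.02325843528   ...  218
exp    0.5   0.6931471806 0.05854638141   0.002316009548  0.06301338005   ...  582
```

Each `gamma_hat ± 1.96·se` covers the closed-form `gamma_theory`, and
the rate rises steeply with milder bottlenecks (larger `D`). Other
entry points: `evopassage simulate {exp,resource,chemostat,genotype}`,
`evopassage variants` (the eight assumption triples over a `D` grid),
`evopassage fixtures` (small seeded regression runs). All output is
TSV; any flag can come from a flat `key = value` config file.

From Python:

```python
from evopassage import CoreParams, fixation_rate_exact, optimal_D_fixed_tau

core = CoreParams.stable(D=0.1)           # tau = ln(1/D)/r
fixation_rate_exact(core).gamma           # 0.02162...
optimal_D_fixed_tau(24.0)                 # OptimalD(D=0.2032, ratio=4.92)
```

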