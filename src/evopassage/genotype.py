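"""Multi-locus genotype simulator exhibiting clonal interference.

Beneficial mutations occur at one of a small fixed number of loci, so a
genome is a bitmask of mutated loci and multiple segregating mutations can
co-occur or compete.  Fitness is multiplicative: a genotype ``g`` divides
at rate ``r_bar * prod_{locus in g} (1 + s_locus)``.  Growth phases use the
exact Yule transition law per genotype; bottlenecks thin each genotype
binomially.

Because an adapting population outgrows a fixed dilution factor once
mutants dominate (the net growth rate exceeds the wild type's), the
bottleneck here dilutes *to the target size*: per-cell survival
``min(1, D * N / total)``, which equals ``D`` while the population is at
its equilibrium and emulates the resource ceiling of a real serial-passage
protocol.  This keeps arbitrarily long runs bounded so allele fixation
(mutant frequency above a threshold, default 0.99) can be observed.

Locus effects are drawn once per run ("quenched") from an exponential
distribution with mean ``omega``, or fixed to a common value.  Back
mutation and double mutations within a single division are ignored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .theory import survival_initial

__all__ = [
    "GenotypeConfig",
    "GenotypeState",
    "GenotypeResult",
    "run_genotype_experiment",
]


@dataclass(frozen=True)
class GenotypeConfig:
    """Loci, effects and mutation supply of the genome-based model.

    ``mu_locus`` is the mutation probability per locus per division.
    ``locus_effects`` fixes the per-locus selective effects; when ``None``
    they are drawn per replicate from Exponential(mean ``omega``).
    """

    n_loci: int = 10
    omega: float = 0.1
    mu_locus: float = 1e-9
    locus_effects: tuple[float, ...] | None = None
    fixation_freq: float = 0.99
    establish_threshold_prob: float = 1e-6

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if self.locus_effects is not None:
            if len(self.locus_effects) != self.n_loci:
                raise ValueError("locus_effects must have one entry per locus")
            if any(s <= 0 for s in self.locus_effects):
                raise ValueError("locus effects must be positive")
        if not 0.0 < self.fixation_freq <= 1.0:
            raise ValueError("fixation_freq must lie in (0, 1]")


@dataclass
class GenotypeState:
    """Counts per genotype bitmask (0 = wild type)."""

    counts: dict[int, int]
    t: float = 0.0

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class GenotypeResult:
    fixations_per_hour: float
    mean_fixed_s: float
    locus_fixation_times: list[dict[int, float]]   # per replicate: locus -> time
    locus_establish_times: list[dict[int, float]]
    mean_fitness_trajectory: np.ndarray            # (n_cycles,) replicate average
    locus_effects: np.ndarray                      # (n_replicates, n_loci)
    per_replicate_fixations: np.ndarray
    t_end: float


def _fitness(mask: int, effects: np.ndarray, cache: dict[int, float]) -> float:
    w = cache.get(mask)
    if w is None:
        w = 1.0
        m, i = mask, 0
        while m:
            if m & 1:
                w *= 1.0 + effects[i]
            m >>= 1
            i += 1
        cache[mask] = w
    return w


def _growth_phase(state: GenotypeState, effects: np.ndarray, wcache: dict,
                  r_bar: float, tau: float, mu_locus: float, n_loci: int,
                  rng: np.random.Generator, mutation: bool) -> None:
    new_counts: dict[int, int] = {}
    children: dict[int, int] = {}
    for mask, n in state.counts.items():
        w = _fitness(mask, effects, wcache)
        rate = r_bar * w
        p = math.exp(-rate * tau)
        n_end = n + int(rng.negative_binomial(n, p)) if n > 0 else 0
        n_div = n_end - n
        if mutation and mu_locus > 0.0 and n_div > 0:
            growth = math.expm1(rate * tau)
            for locus in range(n_loci):
                bit = 1 << locus
                if mask & bit:
                    continue  # no back mutation, single hit per locus
                n_mut = int(rng.binomial(n_div, mu_locus))
                for _ in range(n_mut):
                    t_m = math.log1p(rng.random() * growth) / rate
                    w_child = w * (1.0 + effects[locus])
                    beta = max(math.exp(-r_bar * w_child * (tau - t_m)), 1e-300)
                    size = int(rng.geometric(beta))
                    child_mask = mask | bit
                    children[child_mask] = children.get(child_mask, 0) + size
                    n_end = max(n_end - 1, 0)  # the mutant daughter leaves the class
        if n_end > 0:
            new_counts[mask] = n_end
    for mask, n in children.items():
        new_counts[mask] = new_counts.get(mask, 0) + n
    state.counts = new_counts
    state.t += tau


def _bottleneck(state: GenotypeState, D: float, target_survivors: float,
                stabilize: bool, rng: np.random.Generator) -> None:
    """Binomial thinning; with ``stabilize`` the per-cell survival adapts so
    the expected number of survivors is ``target_survivors`` (= D*N), which
    equals plain Bernoulli(D) thinning while the population sits at N."""
    total = state.total
    if total == 0:
        return
    p = min(1.0, target_survivors / total) if stabilize else D
    new_counts = {}
    for mask, n in state.counts.items():
        m = int(rng.binomial(n, p))
        if m > 0:
            new_counts[mask] = m
    state.counts = new_counts


def _allele_counts(state: GenotypeState, n_loci: int) -> np.ndarray:
    out = np.zeros(n_loci, dtype=np.int64)
    for mask, n in state.counts.items():
        m, i = mask, 0
        while m:
            if m & 1:
                out[i] += n
            m >>= 1
            i += 1
    return out


def run_genotype_experiment(config: GenotypeConfig, *, D: float,
                            r_bar: float = 1.0, N: float = 1e5,
                            tau: float | None = None, t_end: float = 200.0,
                            n_replicates: int = 10, seed: int = 0,
                            stabilize: bool = True) -> GenotypeResult:
    """Serial-passage evolution of a multi-locus asexual genome.

    ``tau`` defaults to ``ln(1/D) / r_bar`` (matched average growth rate).
    A locus counts as *fixed* once its mutant-allele frequency exceeds
    ``config.fixation_freq`` across the whole population, and as
    *established* once the allele count crosses the same extinction-bound
    threshold used by the lineage simulators.  Reports locus fixations per
    hour, the mean effect of fixed loci, and the mean-fitness trajectory.
    """
    if not 0.0 < D < 1.0:
        raise ValueError("D must lie in (0, 1)")
    if tau is None:
        tau = math.log(1.0 / D) / r_bar
    n_cycles = int(t_end / tau + 1e-9)
    streams = np.random.SeedSequence(seed).spawn(n_replicates)

    fix_times: list[dict[int, float]] = []
    est_times: list[dict[int, float]] = []
    all_effects = np.empty((n_replicates, config.n_loci))
    fitness_traj = np.zeros(n_cycles)
    n_fix = np.zeros(n_replicates)
    fixed_s: list[float] = []

    for rep, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        effects = (np.asarray(config.locus_effects, dtype=float)
                   if config.locus_effects is not None
                   else rng.exponential(config.omega, size=config.n_loci))
        all_effects[rep] = effects
        log_v = np.array([math.log(survival_initial(float(s), D)) for s in effects])
        est_need = math.log(config.establish_threshold_prob) / log_v  # allele counts
        wcache: dict[int, float] = {0: 1.0}
        state = GenotypeState(counts={0: int(round(D * N))})
        fixed: dict[int, float] = {}
        estab: dict[int, float] = {}
        for c in range(n_cycles):
            _growth_phase(state, effects, wcache, r_bar, tau, config.mu_locus,
                          config.n_loci, rng, mutation=True)
            _bottleneck(state, D, D * N, stabilize, rng)
            total = state.total
            if total == 0:
                break
            alleles = _allele_counts(state, config.n_loci)
            for locus in range(config.n_loci):
                if locus not in estab and alleles[locus] > est_need[locus]:
                    estab[locus] = state.t
                if locus not in fixed and alleles[locus] >= config.fixation_freq * total:
                    fixed[locus] = state.t
                    n_fix[rep] += 1
                    fixed_s.append(float(effects[locus]))
            w_mean = sum(_fitness(m, effects, wcache) * n
                         for m, n in state.counts.items()) / total
            fitness_traj[c] += w_mean / n_replicates
        fix_times.append(fixed)
        est_times.append(estab)

    return GenotypeResult(
        fixations_per_hour=float(np.mean(n_fix)) / (n_cycles * tau),
        mean_fixed_s=float(np.mean(fixed_s)) if fixed_s else math.nan,
        locus_fixation_times=fix_times,
        locus_establish_times=est_times,
        mean_fitness_trajectory=fitness_traj,
        locus_effects=all_effects,
        per_replicate_fixations=n_fix,
        t_end=n_cycles * tau,
    )
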