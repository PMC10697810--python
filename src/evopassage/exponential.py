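"""Stochastic simulator of serial passage with resource-unconstrained growth.

The wild type and every mutant lineage are independent pure-birth (Yule)
processes; bottlenecks thin each compartment binomially with per-cell
survival probability ``D``.  Beneficial mutations arise at wild-type
divisions with probability ``mu`` and draw their selective effect from an
exponential distribution with mean ``omega`` (or a point mass, for
validation runs).

Two engines share one interface:

* the default engine samples each growth phase *exactly* from the Yule
  transition law — a compartment of ``n`` cells after ``u`` hours at rate
  ``lam`` is ``n + NegativeBinomial(n, e^{-lam u})`` — so phases advance in
  O(1) draws per compartment at any population size; mutation arrival
  times are drawn from the (deterministic-intensity) inhomogeneous Poisson
  profile of wild-type divisions, an approximation that is negligible at
  the default ``N = 1e9``;
* ``exact_mode`` simulates every division of every cell event-by-event
  (Gillespie) and is used to validate the default engine at small ``N``.

A lineage is counted as destined to fix ("established") once its
eventual-extinction bound ``V(0, s)^size``, evaluated at phase starts,
drops below a configurable threshold.  Mutations are generated only inside
the measurement window; cycling then continues without mutation until every
pending lineage has resolved, so the estimated rate refers to mutations
*occurring* per hour that go on to fix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .theory import CoreParams, survival_initial

__all__ = [
    "MutantLineage",
    "PopulationState",
    "SimConfig",
    "SimResult",
    "FixedMutationStats",
    "run_growth_phase",
    "apply_bottleneck",
    "run_experiment",
    "fixed_mutation_stats",
]

_COUNT_OVERFLOW = 10 ** 15


@dataclass
class MutantLineage:
    """One beneficial-mutant clone and its bookkeeping.

    ``t_origin`` is absolute simulation time of the founding division;
    ``t_phase`` the origin time within its growth phase.  ``fate`` is one
    of ``segregating``, ``extinct``, ``established``.
    """

    id: int
    s: float
    t_origin: float
    t_phase: float
    size: int
    fate: str = "segregating"
    log_v: float = 0.0  # cached ln V(0, s) for the establishment test
    t_established: float = float("nan")


@dataclass
class PopulationState:
    wildtype: int
    lineages: list[MutantLineage] = field(default_factory=list)
    t: float = 0.0
    next_id: int = 0


@dataclass(frozen=True)
class SimConfig:
    """Configuration of a serial-passage experiment.

    ``t_end`` is the measurement window in hours (only whole growth cycles
    are simulated: ``floor(t_end / tau)`` of them).  ``fixed_s`` replaces
    the exponential effect distribution with a point mass, for validation.
    """

    core: CoreParams
    t_end: float = 50.0
    n_replicates: int = 200
    seed: int = 0
    exact_mode: bool = False
    establish_threshold_prob: float = 1e-6
    fixed_s: float | None = None
    record_trajectory: bool = False
    max_resolution_cycles: int = 400

    def __post_init__(self) -> None:
        if self.t_end < self.core.tau:
            raise ValueError("t_end must cover at least one growth period")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0.0 < self.establish_threshold_prob < 1.0:
            raise ValueError("establish_threshold_prob must lie in (0, 1)")


@dataclass
class SimResult:
    """Replicate-averaged adaptation-rate estimate plus the raw material
    for the fixed-mutation summaries."""

    gamma_hat: float
    se: float
    per_replicate_gamma: np.ndarray
    fixed_effects: np.ndarray        # s of established mutations, pooled
    origin_phases: np.ndarray        # within-phase origin times of the same
    n_established: int
    unresolved_mass: float           # sum of survival prob. of lineages past the cap
    first_establishment_times: np.ndarray  # per replicate crossing time; NaN if none
    config: SimConfig
    trajectory: list[tuple[int, float, str, float, int]] | None = None


@dataclass(frozen=True)
class FixedMutationStats:
    mean_s: float
    ratio_to_omega: float
    ks_statistic: float
    ks_pvalue: float


# ---------------------------------------------------------------------------
# Phase-level operations
# ---------------------------------------------------------------------------

def _draw_effect(core: CoreParams, fixed_s: float | None, rng: np.random.Generator) -> float:
    return fixed_s if fixed_s is not None else float(rng.exponential(core.omega))


def _grow_count(n: int, rate: float, duration: float, rng: np.random.Generator) -> int:
    """Exact Yule transition: n cells for `duration` hours at per-capita
    `rate` become n + NegBinomial(n, e^{-rate*duration})."""
    if n == 0 or duration == 0.0:
        return n
    p = math.exp(-rate * duration)
    return n + int(rng.negative_binomial(n, p))


def _growth_phase_sampled(state: PopulationState, core: CoreParams,
                          rng: np.random.Generator, *, duration: float,
                          mutation: bool, fixed_s: float | None) -> None:
    r, tau = core.r, duration
    new_wt = _grow_count(state.wildtype, r, tau, rng)
    n_div = new_wt - state.wildtype
    state.wildtype = new_wt
    if state.wildtype > _COUNT_OVERFLOW:
        raise OverflowError(
            "population count overflow; use a smaller N or shorter t_end")

    for lin in state.lineages:
        lin.size = _grow_count(lin.size, r * (1.0 + lin.s), tau, rng)

    if mutation and core.mu > 0.0 and n_div > 0:
        n_mut = int(rng.binomial(n_div, core.mu))
        if n_mut:
            growth = math.expm1(r * tau)
            u = rng.random(n_mut)
            t_m = np.log1p(u * growth) / r  # division times have density ~ e^{rt}
            for tm in t_m:
                s = _draw_effect(core, fixed_s, rng)
                beta = max(math.exp(-r * (1.0 + s) * (tau - tm)), 1e-300)
                size = int(rng.geometric(beta))
                state.lineages.append(MutantLineage(
                    id=state.next_id, s=s, t_origin=state.t + float(tm),
                    t_phase=float(tm), size=size,
                    log_v=math.log(survival_initial(s, core.D)),
                ))
                state.next_id += 1


def _growth_phase_exact(state: PopulationState, core: CoreParams,
                        rng: np.random.Generator, *, duration: float,
                        mutation: bool, fixed_s: float | None) -> None:
    """Per-cell Gillespie simulation of one growth phase (small N only)."""
    r = core.r
    t_loc = 0.0
    founders: list[MutantLineage] = []
    while True:
        lin_rates = [r * (1.0 + lin.s) * lin.size for lin in state.lineages]
        lin_rates += [r * (1.0 + lin.s) * lin.size for lin in founders]
        total = r * state.wildtype + sum(lin_rates)
        if total == 0.0:
            break
        t_loc += rng.exponential(1.0 / total)
        if t_loc >= duration:
            break
        u = rng.random() * total
        if u < r * state.wildtype:
            if mutation and core.mu > 0.0 and rng.random() < core.mu:
                s = _draw_effect(core, fixed_s, rng)
                founders.append(MutantLineage(
                    id=state.next_id, s=s, t_origin=state.t + t_loc,
                    t_phase=t_loc, size=1,
                    log_v=math.log(survival_initial(s, core.D)),
                ))
                state.next_id += 1
            else:
                state.wildtype += 1
        else:
            u -= r * state.wildtype
            pool = state.lineages + founders
            for lin, rate in zip(pool, lin_rates):
                if u < rate:
                    lin.size += 1
                    break
                u -= rate
    state.lineages.extend(founders)


def run_growth_phase(state: PopulationState, core: CoreParams,
                     rng: np.random.Generator, *, duration: float | None = None,
                     exact_mode: bool = False, mutation: bool = True,
                     fixed_s: float | None = None) -> PopulationState:
    """Advance the population (in place) by one growth period.

    ``duration`` defaults to ``core.tau``; ``duration = 0`` is the identity.
    Returns `state` for convenience.
    """
    d = core.tau if duration is None else duration
    if d < 0:
        raise ValueError("duration must be non-negative")
    if d == 0.0:
        return state
    if exact_mode:
        _growth_phase_exact(state, core, rng, duration=d,
                            mutation=mutation, fixed_s=fixed_s)
    else:
        _growth_phase_sampled(state, core, rng, duration=d,
                              mutation=mutation, fixed_s=fixed_s)
    state.t += d
    return state


def apply_bottleneck(state: PopulationState, D: float,
                     rng: np.random.Generator) -> PopulationState:
    """Thin every compartment independently: each count is replaced by a
    Binomial(count, D) draw, so no compartment can grow through a
    bottleneck (unlike under the Poisson approximation)."""
    if not 0.0 < D < 1.0:
        raise ValueError("D must lie in (0, 1)")
    state.wildtype = int(rng.binomial(state.wildtype, D))
    for lin in state.lineages:
        if lin.size > 0:
            lin.size = int(rng.binomial(lin.size, D))
        if lin.size == 0 and lin.fate == "segregating":
            lin.fate = "extinct"
    return state


# ---------------------------------------------------------------------------
# Full experiment
# ---------------------------------------------------------------------------

def _classify(state: PopulationState, log_thresh: float,
              established: list[MutantLineage]) -> None:
    """At a phase start, promote lineages whose extinction bound V^size has
    crossed the threshold and drop extinct ones."""
    still = []
    for lin in state.lineages:
        if lin.size == 0:
            lin.fate = "extinct"
        elif lin.size * lin.log_v < log_thresh:
            lin.fate = "established"
            lin.t_established = state.t
            established.append(lin)
        else:
            still.append(lin)
    state.lineages = still


def _run_replicate(config: SimConfig, rng: np.random.Generator,
                   rep_index: int, trajectory: list | None):
    core = config.core
    n_cycles = int(config.t_end / core.tau + 1e-9)
    t_sim = n_cycles * core.tau
    log_thresh = math.log(config.establish_threshold_prob)

    state = PopulationState(wildtype=int(round(core.D * core.N)))
    established: list[MutantLineage] = []

    def record() -> None:
        if trajectory is not None:
            trajectory.append((rep_index, state.t, "wt", 0.0, state.wildtype))
            for lin in state.lineages:
                trajectory.append((rep_index, state.t, f"mutant_{lin.id}",
                                   lin.s, lin.size))

    record()
    for _ in range(n_cycles):
        run_growth_phase(state, core, rng, exact_mode=config.exact_mode,
                         mutation=True, fixed_s=config.fixed_s)
        record()
        apply_bottleneck(state, core.D, rng)
        _classify(state, log_thresh, established)
        record()
        if state.wildtype == 0 and not state.lineages:
            break

    # Resolve pending lineages: no new mutations, keep cycling.
    extra = 0
    while state.lineages and extra < config.max_resolution_cycles:
        run_growth_phase(state, core, rng, exact_mode=config.exact_mode,
                         mutation=False)
        apply_bottleneck(state, core.D, rng)
        _classify(state, log_thresh, established)
        extra += 1
    unresolved = sum(-math.expm1(lin.size * lin.log_v) for lin in state.lineages)

    gamma = (len(established) + unresolved) / t_sim
    first = min((lin.t_established for lin in established), default=math.nan)
    return gamma, established, unresolved, first, t_sim


def run_experiment(config: SimConfig) -> SimResult:
    """Run ``n_replicates`` independent serial-passage experiments and
    estimate the adaptation rate as established mutations per hour of
    measurement window (see module docstring for the counting rule).

    Fully reproducible: replicate ``k`` uses the ``k``-th child stream of
    ``SeedSequence(config.seed)``.
    """
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    gammas = np.empty(config.n_replicates)
    firsts = np.empty(config.n_replicates)
    all_estab: list[MutantLineage] = []
    unresolved_total = 0.0
    trajectory: list | None = [] if config.record_trajectory else None

    for k, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        gamma, established, unresolved, first, _ = _run_replicate(
            config, rng, k, trajectory)
        gammas[k] = gamma
        firsts[k] = first
        unresolved_total += unresolved
        all_estab.extend(established)

    se = (float(np.std(gammas, ddof=1)) / math.sqrt(len(gammas))
          if len(gammas) > 1 else 0.0)
    return SimResult(
        gamma_hat=float(np.mean(gammas)),
        se=se,
        per_replicate_gamma=gammas,
        fixed_effects=np.array([lin.s for lin in all_estab]),
        origin_phases=np.array([lin.t_phase for lin in all_estab]),
        n_established=len(all_estab),
        unresolved_mass=unresolved_total,
        first_establishment_times=firsts,
        config=config,
        trajectory=trajectory,
    )


def fixed_mutation_stats(result: SimResult,
                         omega: float | None = None) -> FixedMutationStats:
    """Summaries of the mutations that established: mean selective effect,
    its ratio to ``omega`` (theory predicts ~2), and a Kolmogorov-Smirnov
    comparison of within-phase origin times against Uniform(0, tau)."""
    from scipy import stats

    if result.n_established == 0:
        raise ValueError("no established mutations recorded")
    if omega is None:
        omega = result.config.core.omega
    tau = result.config.core.tau
    mean_s = float(np.mean(result.fixed_effects))
    ks = stats.kstest(result.origin_phases, stats.uniform(loc=0, scale=tau).cdf)
    return FixedMutationStats(mean_s=mean_s, ratio_to_omega=mean_s / omega,
                              ks_statistic=float(ks.statistic),
                              ks_pvalue=float(ks.pvalue))
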