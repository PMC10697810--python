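"""Resource-explicit growth: Monod kinetics, serial transfer, chemostat.

Growth is limited by a single resource: the per-cell division rate is the
Monod function ``r_max * R / (k + R)`` of the current resource
concentration ``R``, and every division consumes exactly one unit of
resource.  In *serial* mode the culture grows for ``tau`` hours, then a
fraction ``D`` of cells (binomially, per cell) is transferred into fresh
media, the resource mixing volumetrically to ``D * R_end + (1 - D) * R0``
(or being fully replaced by ``R0``, switchable).  In *chemostat* mode there
are no bottlenecks: cells wash out at per-capita rate ``Phi`` while fresh
media flows in at the same rate.

Dynamics advance by Poisson tau-leaping with an adaptive step: the step is
capped so that the expected per-capita growth and the expected resource
drawdown per step stay below a small fraction (default 5%) of the current
values, with a floor of ``tau / max_steps_per_phase``.  All replicates run
simultaneously as NumPy arrays; mutant lineages live in flat arrays keyed
by replicate.  Divisions are integer events, so resource bookkeeping obeys
an exact per-phase mass balance (divisions == resource consumed).

Establishment counting follows the exponential-growth simulator: a mutant
lineage is destined to fix once ``V(0, s)^size`` drops below a threshold at
a phase start, with ``V`` evaluated from the average-growth-rate theory
(serial) or the classic birth-death extinction probability ``1/(1+s)``
(chemostat).  Mutations arise only inside the measurement window; cycling
continues without mutation afterwards until pending lineages resolve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .theory import survival_initial

__all__ = [
    "ResourceParams",
    "ResourceState",
    "EquilibriumSummary",
    "ResourceSimResult",
    "monod_rate",
    "step_kinetics",
    "advance_resource_phase",
    "apply_transfer",
    "run_serial_resource",
    "run_chemostat",
]


@dataclass(frozen=True)
class ResourceParams:
    """Monod parameters plus the dilution mode.

    ``r_max`` per hour; ``k`` is the half-saturation resource concentration
    (units of resource = cell divisions); ``R0`` the fresh-media
    concentration.  ``dilution_rate`` (Phi, per hour) applies in chemostat
    mode only and must stay below the maximum attainable growth rate
    ``r_max R0 / (k + R0)`` or the culture washes out.
    ``resource_transfer``: ``"mix"`` (volumetric, D*R_end + (1-D)*R0) or
    ``"replace"`` (fresh media only).
    """

    r_max: float = 3.0
    k: float = 1e9
    R0: float = 1e9
    mode: str = "serial"
    dilution_rate: float | None = None
    resource_transfer: str = "mix"

    def __post_init__(self) -> None:
        if min(self.r_max, self.k, self.R0) <= 0:
            raise ValueError("r_max, k, R0 must be positive")
        if self.mode not in ("serial", "chemostat"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.resource_transfer not in ("mix", "replace"):
            raise ValueError(f"unknown resource_transfer {self.resource_transfer!r}")
        if self.mode == "chemostat":
            if self.dilution_rate is None or self.dilution_rate <= 0:
                raise ValueError("chemostat mode requires a positive dilution_rate")
            if self.dilution_rate >= self.r_max * self.R0 / (self.k + self.R0):
                # Permitted (the simulator must demonstrate washout), but noted.
                pass


@dataclass
class EquilibriumSummary:
    """Equilibrium pre-bottleneck population size N*, the average growth
    rate ``r_bar = ln(1/D)/tau`` (serial mode), and the burn-in record used
    for the stationarity check."""

    N_star: float
    r_bar: float | None
    burn_in_cycles: int
    burn_in_totals: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ResourceSimResult:
    gamma_hat: float
    se: float
    per_replicate_gamma: np.ndarray
    fixed_effects: np.ndarray
    origin_phases: np.ndarray
    n_established: int
    unresolved_mass: float
    extinct_fraction: float           # replicates that died out (flagged, not raised)
    t_measure: float
    seed: int
    n_star: float = math.nan          # mean population over the measurement window
    resource_mean: float = math.nan   # mean resource level over the same window


class ResourceState:
    """Vectorized population + resource state over ``n`` replicates."""

    def __init__(self, n_replicates: int, wt0: int, R0: float):
        self.n = n_replicates
        self.wildtype = np.full(n_replicates, wt0, dtype=np.int64)
        self.resource = np.full(n_replicates, float(R0))
        self.alive = np.ones(n_replicates, dtype=bool)
        self.lin_rep = np.empty(0, dtype=np.int64)
        self.lin_s = np.empty(0)
        self.lin_size = np.empty(0, dtype=np.int64)
        self.lin_t_phase = np.empty(0)
        self.lin_log_v = np.empty(0)
        self.t = 0.0

    @property
    def totals(self) -> np.ndarray:
        return self.wildtype + np.bincount(
            self.lin_rep, weights=self.lin_size, minlength=self.n).astype(np.int64)

    def add_lineages(self, rep, s, t_phase, log_v) -> None:
        m = len(rep)
        self.lin_rep = np.concatenate([self.lin_rep, rep])
        self.lin_s = np.concatenate([self.lin_s, s])
        self.lin_size = np.concatenate([self.lin_size, np.ones(m, dtype=np.int64)])
        self.lin_t_phase = np.concatenate([self.lin_t_phase, t_phase])
        self.lin_log_v = np.concatenate([self.lin_log_v, log_v])

    def compact(self, keep: np.ndarray) -> None:
        self.lin_rep = self.lin_rep[keep]
        self.lin_s = self.lin_s[keep]
        self.lin_size = self.lin_size[keep]
        self.lin_t_phase = self.lin_t_phase[keep]
        self.lin_log_v = self.lin_log_v[keep]


def monod_rate(params: ResourceParams, R) -> np.ndarray | float:
    """Per-cell division rate ``r_max R / (k + R)``; zero at ``R = 0``."""
    R = np.maximum(np.asarray(R, dtype=float), 0.0)
    out = params.r_max * R / (params.k + R)
    return out if out.shape else float(out)


def step_kinetics(state: ResourceState, params: ResourceParams, dt: float,
                  rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """One Poisson tau-leap of `dt` hours of Monod-limited division.

    Every compartment draws Poisson(rate * count * dt) divisions at the
    rate set by the *current* resource level; each division decrements the
    resource by exactly one unit and the resource never goes negative
    (draws are truncated at the available supply, wild type first).
    Returns ``(wildtype_divisions, total_divisions)`` per replicate.
    """
    g = np.where(state.alive, monod_rate(params, state.resource), 0.0)
    d_wt = rng.poisson(g * state.wildtype * dt)
    has_lineages = len(state.lin_rep) > 0
    if has_lineages:
        lam = g[state.lin_rep] * (1.0 + state.lin_s) * state.lin_size * dt
        d_lin = rng.poisson(lam)
        lin_tot = np.bincount(state.lin_rep, weights=d_lin,
                              minlength=state.n).astype(np.int64)
    else:
        d_lin = np.empty(0, dtype=np.int64)
        lin_tot = np.zeros(state.n, dtype=np.int64)

    avail = np.floor(state.resource).astype(np.int64)
    total = d_wt + lin_tot
    over = np.nonzero(total > avail)[0]
    for idx in over:  # rare: the adaptive step keeps drawdown ~5% of R
        excess = int(total[idx] - avail[idx])
        take = min(excess, int(d_wt[idx]))
        d_wt[idx] -= take
        excess -= take
        if excess > 0:
            rows = np.nonzero(state.lin_rep == idx)[0]
            for row in rows:
                take = min(excess, int(d_lin[row]))
                d_lin[row] -= take
                excess -= take
                if excess == 0:
                    break
        total[idx] = avail[idx]

    state.wildtype += d_wt
    if has_lineages:
        state.lin_size += d_lin
    state.resource -= total
    return d_wt, total


def _adaptive_dt(state: ResourceState, params: ResourceParams, remaining: float,
                 eps: float, floor: float, extra_rate: float = 0.0) -> float:
    g = monod_rate(params, state.resource)
    s_max = float(state.lin_s.max()) if len(state.lin_s) else 0.0
    g_cap = float(np.max(g * state.alive)) * (1.0 + s_max) + extra_rate
    dt = remaining
    if g_cap > 0:
        dt = min(dt, eps / g_cap)
    cons = g * state.wildtype
    if len(state.lin_rep):
        cons = cons + np.bincount(
            state.lin_rep, weights=g[state.lin_rep] * (1.0 + state.lin_s) * state.lin_size,
            minlength=state.n)
    mask = state.alive & (cons > 0)
    if mask.any():
        # Drawdown cap keeps the Monod rate accurate over a step; the small
        # additive slack (0.1% of k) lets the depleted tail coarsen, where
        # the remaining divisions are a negligible share of the budget.
        slack = 1e-3 * params.k
        dt = min(dt, float(np.min(eps * (state.resource[mask] + slack)
                                  / cons[mask])))
    return max(min(remaining, floor), min(dt, remaining))


def advance_resource_phase(state: ResourceState, params: ResourceParams,
                           tau: float, rng: np.random.Generator, *,
                           mu: float = 0.0, omega: float = 0.1,
                           fixed_s: float | None = None, mutation: bool = False,
                           log_v_of_s=None, eps: float = 0.05,
                           max_steps_per_phase: int = 1500) -> np.ndarray:
    """Advance all replicates through one growth period of ``tau`` hours.

    Returns the per-replicate division totals for the phase (equal, by
    construction, to the resource consumed: an exact mass balance).
    ``log_v_of_s`` maps a selective effect to the log extinction
    probability cached on each new lineage (for later establishment tests).
    """
    divisions = np.zeros(state.n, dtype=np.int64)
    floor = tau / max_steps_per_phase
    t_loc = 0.0
    while t_loc < tau * (1.0 - 1e-12):
        dt = _adaptive_dt(state, params, tau - t_loc, eps, floor)
        d_wt, total = step_kinetics(state, params, dt, rng)
        divisions += total
        if mutation and mu > 0.0:
            n_mut = rng.binomial(d_wt, mu)
            hot = np.nonzero(n_mut > 0)[0]
            if len(hot):
                rep = np.repeat(hot, n_mut[hot])
                m = len(rep)
                s = (np.full(m, fixed_s) if fixed_s is not None
                     else rng.exponential(omega, size=m))
                t_phase = t_loc + dt * rng.random(m)
                log_v = np.array([log_v_of_s(x) for x in s])
                state.add_lineages(rep, s, t_phase, log_v)
        t_loc += dt
    state.t += tau
    return divisions


def apply_transfer(state: ResourceState, D: float, params: ResourceParams,
                   rng: np.random.Generator) -> None:
    """Serial transfer: binomial thinning of every compartment and dilution
    of the spent media into fresh media."""
    if not 0.0 < D < 1.0:
        raise ValueError("D must lie in (0, 1)")
    a = state.alive
    state.wildtype[a] = rng.binomial(state.wildtype[a], D)
    if len(state.lin_rep):
        state.lin_size = rng.binomial(state.lin_size, D)
    if params.resource_transfer == "mix":
        state.resource[a] = D * state.resource[a] + (1.0 - D) * params.R0
    else:
        state.resource[a] = params.R0


def _classify(state: ResourceState, log_thresh: float, est_per_rep: np.ndarray,
              fixed_effects: list, origin_phases: list) -> None:
    if not len(state.lin_rep):
        return
    est = state.lin_size * state.lin_log_v < log_thresh
    ext = state.lin_size == 0
    if est.any():
        np.add.at(est_per_rep, state.lin_rep[est], 1)
        fixed_effects.extend(state.lin_s[est].tolist())
        origin_phases.extend(state.lin_t_phase[est].tolist())
    state.compact(~(est | ext))


def run_serial_resource(*, D: float, tau: float, resource: ResourceParams,
                        mu: float = 1e-9, omega: float = 0.1,
                        n_replicates: int = 100, measure_cycles: int = 40,
                        burn_in: int = 10, seed: int = 0,
                        init_pop: int | None = None,
                        establish_threshold_prob: float = 1e-6,
                        fixed_s: float | None = None, eps: float = 0.05,
                        max_steps_per_phase: int = 1500,
                        max_resolution_cycles: int = 400,
                        ) -> tuple[ResourceSimResult, EquilibriumSummary]:
    """Serial-passage experiment with Monod-limited growth.

    ``D`` and ``tau`` vary independently (no stability constraint); the
    population finds its own equilibrium size ``N*`` against the resource
    supply during ``burn_in`` cycles (mutation disabled), after which
    mutations are generated for ``measure_cycles`` cycles and the
    adaptation rate is counted as in the exponential simulator.  Replicate
    extinction is flagged in ``extinct_fraction``, never raised.
    """
    if not 0.0 < D < 1.0 or tau <= 0:
        raise ValueError("need D in (0, 1) and tau > 0")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    wt0 = int(round(D * resource.R0)) if init_pop is None else init_pop
    state = ResourceState(n_replicates, max(wt0, 1), resource.R0)
    log_thresh = math.log(establish_threshold_prob)

    def log_v_of_s(s: float) -> float:
        return math.log(survival_initial(s, D)) if s > 0 else 0.0

    kw = dict(mu=mu, omega=omega, fixed_s=fixed_s, log_v_of_s=log_v_of_s,
              eps=eps, max_steps_per_phase=max_steps_per_phase)

    burn_totals = np.empty((burn_in, n_replicates))
    for c in range(burn_in):
        advance_resource_phase(state, resource, tau, rng, mutation=False, **kw)
        burn_totals[c] = state.totals
        apply_transfer(state, D, resource, rng)
        state.alive &= state.totals > 0

    est_per_rep = np.zeros(n_replicates, dtype=np.int64)
    fixed_effects: list[float] = []
    origin_phases: list[float] = []
    n_star_acc = []
    for _ in range(measure_cycles):
        advance_resource_phase(state, resource, tau, rng, mutation=True, **kw)
        n_star_acc.append(state.totals[state.alive])
        apply_transfer(state, D, resource, rng)
        _classify(state, log_thresh, est_per_rep, fixed_effects, origin_phases)
        state.alive &= state.totals > 0

    extra = 0
    while len(state.lin_rep) and extra < max_resolution_cycles:
        advance_resource_phase(state, resource, tau, rng, mutation=False, **kw)
        apply_transfer(state, D, resource, rng)
        _classify(state, log_thresh, est_per_rep, fixed_effects, origin_phases)
        extra += 1
    unresolved = np.zeros(n_replicates)
    if len(state.lin_rep):
        np.add.at(unresolved, state.lin_rep,
                  -np.expm1(state.lin_size * state.lin_log_v))

    t_measure = measure_cycles * tau
    gammas = (est_per_rep + unresolved) / t_measure
    alive = state.alive
    g_alive = gammas[alive] if alive.any() else np.array([math.nan])
    se = (float(np.std(g_alive, ddof=1)) / math.sqrt(len(g_alive))
          if len(g_alive) > 1 else 0.0)
    pooled_n_star = (np.concatenate(n_star_acc) if n_star_acc
                     else np.empty(0))
    n_star = float(np.mean(pooled_n_star)) if pooled_n_star.size else math.nan
    result = ResourceSimResult(
        gamma_hat=float(np.mean(g_alive)), se=se, per_replicate_gamma=gammas,
        fixed_effects=np.array(fixed_effects), origin_phases=np.array(origin_phases),
        n_established=int(est_per_rep.sum()), unresolved_mass=float(unresolved.sum()),
        extinct_fraction=float(1.0 - alive.mean()), t_measure=t_measure, seed=seed,
        n_star=n_star,
    )
    summary = EquilibriumSummary(
        N_star=n_star, r_bar=math.log(1.0 / D) / tau, burn_in_cycles=burn_in,
        burn_in_totals=burn_totals,
    )
    return result, summary


def run_chemostat(*, resource: ResourceParams, mu: float = 1e-9,
                  omega: float = 0.1, n_replicates: int = 20,
                  t_measure: float = 100.0, burn_in_time: float | None = None,
                  seed: int = 0, init_pop: int | None = None,
                  establish_threshold_prob: float = 1e-6,
                  fixed_s: float | None = None, eps: float = 0.05,
                  check_every: float = 1.0, max_resolution_time: float = 2000.0,
                  ) -> ResourceSimResult:
    """Continuous-culture experiment: no bottlenecks, constant media inflow
    and per-capita washout at rate ``Phi = dilution_rate``.

    Establishment uses the birth-death extinction probability
    ``V = 1/(1+s)`` of a mutant in a population at its steady state (where
    the per-capita division rate equals ``Phi``).  Washout of a replicate
    is flagged in ``extinct_fraction``.
    """
    if resource.mode != "chemostat":
        raise ValueError("resource.mode must be 'chemostat'")
    phi = float(resource.dilution_rate)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    r_eq = resource.k * phi / max(resource.r_max - phi, 1e-12)
    n_eq = max(resource.R0 - r_eq, 1.0)
    wt0 = int(round(n_eq)) if init_pop is None else init_pop
    state = ResourceState(n_replicates, max(wt0, 1), resource.R0)
    if r_eq < resource.R0:
        state.resource[:] = r_eq  # start near balance to shorten burn-in
    log_thresh = math.log(establish_threshold_prob)

    est_per_rep = np.zeros(n_replicates, dtype=np.int64)
    fixed_effects: list[float] = []
    origin_phases: list[float] = []
    equil_pop: list[float] = []
    equil_res: list[float] = []

    def run_window(duration: float, mutation: bool) -> None:
        t_loc = 0.0
        next_check = check_every
        while t_loc < duration * (1.0 - 1e-12):
            dt = _adaptive_dt(state, resource, min(duration - t_loc,
                                                   next_check - t_loc + 1e-12),
                              eps, duration / 200000.0, extra_rate=phi)
            d_wt, _ = step_kinetics(state, resource, dt, rng)
            # continuous outflow: each cell washes out w.p. 1 - e^{-phi dt}
            p_out = -math.expm1(-phi * dt)
            a = state.alive
            state.wildtype[a] -= rng.binomial(state.wildtype[a], p_out)
            if len(state.lin_rep):
                state.lin_size -= rng.binomial(state.lin_size, p_out)
            state.resource[a] += phi * (resource.R0 - state.resource[a]) * dt
            if mutation and mu > 0.0:
                n_mut = rng.binomial(d_wt, mu)
                hot = np.nonzero(n_mut > 0)[0]
                if len(hot):
                    rep = np.repeat(hot, n_mut[hot])
                    m = len(rep)
                    s = (np.full(m, fixed_s) if fixed_s is not None
                         else rng.exponential(omega, size=m))
                    log_v = -np.log1p(s)
                    state.add_lineages(rep, s, state.t + t_loc + dt * rng.random(m),
                                       log_v)
            t_loc += dt
            if t_loc >= next_check or t_loc >= duration * (1.0 - 1e-12):
                _classify(state, log_thresh, est_per_rep, fixed_effects,
                          origin_phases)
                state.alive &= state.totals > 0
                if mutation and state.alive.any():  # the measurement window
                    equil_pop.append(float(np.mean(state.totals[state.alive])))
                    equil_res.append(float(np.mean(state.resource[state.alive])))
                next_check += check_every
        state.t += duration

    if burn_in_time is None:
        burn_in_time = 10.0 / phi
    run_window(burn_in_time, mutation=False)
    run_window(t_measure, mutation=True)
    t_res = 0.0
    while len(state.lin_rep) and t_res < max_resolution_time:
        run_window(check_every, mutation=False)
        t_res += check_every
    unresolved = np.zeros(n_replicates)
    if len(state.lin_rep):
        np.add.at(unresolved, state.lin_rep,
                  -np.expm1(state.lin_size * state.lin_log_v))

    gammas = (est_per_rep + unresolved) / t_measure
    alive = state.alive
    g_alive = gammas[alive] if alive.any() else np.array([math.nan])
    se = (float(np.std(g_alive, ddof=1)) / math.sqrt(len(g_alive))
          if len(g_alive) > 1 else 0.0)
    return ResourceSimResult(
        gamma_hat=float(np.mean(g_alive)), se=se, per_replicate_gamma=gammas,
        fixed_effects=np.array(fixed_effects), origin_phases=np.array(origin_phases),
        n_established=int(est_per_rep.sum()), unresolved_mass=float(unresolved.sum()),
        extinct_fraction=float(1.0 - alive.mean()), t_measure=t_measure, seed=seed,
        n_star=(float(np.mean(equil_pop)) if equil_pop else math.nan),
        resource_mean=(float(np.mean(equil_res)) if equil_res else math.nan),
    )
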