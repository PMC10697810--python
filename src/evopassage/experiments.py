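"""Parameter sweeps, variant comparisons, fixtures and config parsing.

Everything here orchestrates the theory and the simulators into tabular
(TSV) output: adaptation-rate sweeps over dilution grids with matched
theoretical rates, the eight-variant comparison, and small deterministic
fixture runs used for regression testing.  Tables are pandas DataFrames
with a stable column order and deterministic row ordering, so a fixed seed
reproduces byte-identical TSV.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import exponential, genotype, resource, theory

__all__ = [
    "SweepSpec",
    "sweep",
    "compare_variants",
    "make_fixtures",
    "read_config",
    "write_tsv",
]

log = logging.getLogger("evopassage")

SWEEP_COLUMNS = ["model", "D", "tau", "gamma_hat", "se", "gamma_theory",
                 "n_star", "n_established", "replicates", "seed", "error"]


@dataclass(frozen=True)
class SweepSpec:
    """A grid of simulation conditions.

    ``tau_grid="coupled"`` ties the growth period to the dilution through
    ``tau = ln(1/D) / r`` (demographic stability); otherwise the grid is
    the Cartesian product of ``D_grid`` and ``tau_grid``.
    """

    model: str = "exp"                     # exp | resource | chemostat | genotype
    D_grid: tuple[float, ...] = (0.01, 0.1, 0.5)
    tau_grid: tuple[float, ...] | str = "coupled"
    replicates: int = 200
    t_end: float = 50.0
    seed: int = 0
    r: float = 1.0
    mu: float = 1e-9
    N: float = 1e9
    omega: float = 0.1
    resource_params: resource.ResourceParams = field(
        default_factory=resource.ResourceParams)

    def __post_init__(self) -> None:
        if self.model not in ("exp", "resource", "chemostat", "genotype"):
            raise ValueError(f"unknown model {self.model!r}")
        if len(self.D_grid) == 0:
            raise ValueError("D_grid must be non-empty")
        if any(not 0.0 < d < 1.0 for d in self.D_grid):
            raise ValueError("all D values must lie in (0, 1)")
        if isinstance(self.tau_grid, str):
            if self.tau_grid != "coupled":
                raise ValueError("tau_grid must be a tuple of hours or 'coupled'")
        elif len(self.tau_grid) == 0:
            raise ValueError("tau_grid must be non-empty")


def _grid_points(spec: SweepSpec) -> list[tuple[float, float]]:
    if isinstance(spec.tau_grid, str):
        return [(d, math.log(1.0 / d) / spec.r) for d in spec.D_grid]
    return [(d, t) for d in spec.D_grid for t in spec.tau_grid]


def sweep(spec: SweepSpec) -> pd.DataFrame:
    """Run the requested simulator on every grid point and attach the
    matching theoretical rate (closed-form exponential approximation, or
    the general resource formula evaluated at the measured N*).

    A failure at one grid point is recorded in its ``error`` column and the
    sweep continues.  Rows are ordered by (D, tau); error bars follow the
    mean +/- 1.96 * se convention.
    """
    points = sorted(_grid_points(spec))
    streams = np.random.SeedSequence(spec.seed).spawn(len(points))
    rows = []
    for (d, tau), stream in zip(points, streams):
        point_seed = int(stream.generate_state(1, np.uint32)[0])
        row = {"model": spec.model, "D": d, "tau": tau, "seed": point_seed,
               "replicates": spec.replicates, "error": ""}
        try:
            row.update(_run_point(spec, d, tau, point_seed))
        except Exception as exc:  # keep sweeping, record the failure
            log.warning("grid point D=%g tau=%g failed: %s", d, tau, exc)
            row.update({"gamma_hat": math.nan, "se": math.nan,
                        "gamma_theory": math.nan, "n_star": math.nan,
                        "n_established": 0, "error": str(exc)})
        rows.append(row)
    return pd.DataFrame(rows, columns=SWEEP_COLUMNS)


def _run_point(spec: SweepSpec, d: float, tau: float, seed: int) -> dict:
    if spec.model == "exp":
        core = theory.CoreParams(r=spec.r, mu=spec.mu, N=spec.N,
                                 omega=spec.omega, D=d, tau=tau)
        core.require_stable()
        res = exponential.run_experiment(exponential.SimConfig(
            core=core, t_end=spec.t_end, n_replicates=spec.replicates, seed=seed))
        return {"gamma_hat": res.gamma_hat, "se": res.se,
                "gamma_theory": theory.fixation_rate_approx(core).gamma,
                "n_star": spec.N, "n_established": res.n_established}
    if spec.model == "resource":
        cycles = max(int(spec.t_end / tau + 1e-9), 1)
        res, summ = resource.run_serial_resource(
            D=d, tau=tau, resource=spec.resource_params, mu=spec.mu,
            omega=spec.omega, n_replicates=spec.replicates,
            measure_cycles=cycles, seed=seed)
        gamma_th = theory.fixation_rate_general(
            tau=tau, mu=spec.mu, N_star=summ.N_star, omega=spec.omega, D=d).gamma
        return {"gamma_hat": res.gamma_hat, "se": res.se,
                "gamma_theory": gamma_th, "n_star": summ.N_star,
                "n_established": res.n_established}
    if spec.model == "chemostat":
        phi = math.log(1.0 / d) / tau  # matched average growth rate
        params = resource.ResourceParams(
            r_max=spec.resource_params.r_max, k=spec.resource_params.k,
            R0=spec.resource_params.R0, mode="chemostat", dilution_rate=phi)
        res = resource.run_chemostat(
            resource=params, mu=spec.mu, omega=spec.omega,
            n_replicates=spec.replicates, t_measure=spec.t_end, seed=seed)
        return {"gamma_hat": res.gamma_hat, "se": res.se,
                "gamma_theory": math.nan, "n_star": math.nan,
                "n_established": res.n_established}
    # genotype
    cfg = genotype.GenotypeConfig(omega=spec.omega, mu_locus=spec.mu)
    res = genotype.run_genotype_experiment(
        cfg, D=d, r_bar=spec.r, N=spec.N, tau=tau, t_end=spec.t_end,
        n_replicates=spec.replicates, seed=seed)
    return {"gamma_hat": res.fixations_per_hour, "se": math.nan,
            "gamma_theory": math.nan, "n_star": spec.N,
            "n_established": int(res.per_replicate_fixations.sum())}


def compare_variants(*, r: float = 1.0, mu: float = 1e-9, N: float = 1e9,
                     omega: float = 0.1,
                     D_grid: tuple[float, ...] = (0.001, 0.01, 0.05, 0.1, 0.2,
                                                  0.35, 0.5, 0.7, 0.9),
                     refine_optimum: bool = False) -> pd.DataFrame:
    """Evaluate all eight assumption variants over a dilution grid (with
    the coupled ``tau = ln(1/D)/r``).

    Returns one row per (variant, D) with the rate, plus each variant's
    grid argmax; with ``refine_optimum`` the continuous optimum over
    ``D in (1e-3, 0.999)`` is added.
    """
    if len(D_grid) == 0:
        raise ValueError("D_grid must be non-empty")
    rows = []
    for variant in theory.VariantSpec.all_variants():
        gammas = []
        for d in sorted(D_grid):
            core = theory.CoreParams.stable(r=r, mu=mu, N=N, omega=omega, D=d)
            gammas.append(theory.variant_rate(core, variant).gamma)
        d_sorted = sorted(D_grid)
        argmax = d_sorted[int(np.argmax(gammas))]
        opt = (theory.optimal_D_variant(variant, r=r, mu=mu, N=N, omega=omega)
               if refine_optimum else (math.nan, math.nan, math.nan))
        for d, g in zip(d_sorted, gammas):
            rows.append({"metric": variant.metric, "growth": variant.growth,
                         "sampling": variant.sampling, "D": d, "gamma": g,
                         "argmax_D_grid": argmax, "optimal_D": opt[0]})
    return pd.DataFrame(rows)


def make_fixtures(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Small deterministic runs (N <= 1e4, inflated mu) with summary tables,
    for regression tests and as worked examples.

    Returns ``{"exp": ..., "exp_trajectory": ..., "genotype": ...}``; every
    value is reproducible byte-for-byte from the seed.
    """
    ss = np.random.SeedSequence(seed)
    s_exp, s_geno = (int(c.generate_state(1, np.uint32)[0]) for c in ss.spawn(2))

    core = theory.CoreParams.stable(r=1.0, mu=2e-5, N=5e3, omega=0.1, D=0.2)
    cfg = exponential.SimConfig(core=core, t_end=5 * core.tau, n_replicates=5,
                                seed=s_exp, record_trajectory=True)
    res = exponential.run_experiment(cfg)
    exp_summary = pd.DataFrame([{
        "D": core.D, "tau": core.tau, "replicates": cfg.n_replicates,
        "gamma_hat": res.gamma_hat, "se": res.se,
        "n_established": res.n_established,
        "mean_fixed_s": (float(np.mean(res.fixed_effects))
                         if res.n_established else math.nan),
    }])
    traj = pd.DataFrame(res.trajectory,
                        columns=["replicate", "time", "compartment", "s", "count"])

    gcfg = genotype.GenotypeConfig(n_loci=3, omega=0.1, mu_locus=2e-5,
                                   locus_effects=(0.15, 0.25, 0.4))
    gres = genotype.run_genotype_experiment(gcfg, D=0.2, r_bar=1.0, N=5e3,
                                            t_end=40.0, n_replicates=3,
                                            seed=s_geno)
    geno = pd.DataFrame([{
        "locus": i, "s": gcfg.locus_effects[i],
        "fixed_time": gres.locus_fixation_times[0].get(i, math.nan)}
        for i in range(gcfg.n_loci)])

    return {"exp": exp_summary, "exp_trajectory": traj, "genotype": geno}


def read_config(path) -> dict[str, str]:
    """Parse a flat key-value config file (``key = value`` or
    ``key: value`` per line; ``#`` comments and blank lines ignored)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in ("=", ":"):
                if sep in line:
                    key, _, value = line.partition(sep)
                    out[key.strip()] = value.strip()
                    break
            else:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
    return out


def write_tsv(df: pd.DataFrame, path_or_buf=None) -> str | None:
    """Write a table as TSV with a header row and no index (the package's
    single tabular output convention)."""
    return df.to_csv(path_or_buf, sep="\t", index=False,
                     float_format="%.10g", lineterminator="\n")
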