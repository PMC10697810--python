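"""Shared fixtures and independent Monte-Carlo oracles.

The oracles here deliberately avoid the package's phase-sampling machinery:
branching replicates are advanced with raw negative-binomial/binomial draws
(the textbook Yule + thinning laws), and the pure-birth oracle simulates
every division event, so they can stand as independent checks on both the
closed-form theory and the simulators.
"""

from __future__ import annotations

import math

import numpy as np
import pytest

from evopassage import CoreParams


@pytest.fixture
def core_d01() -> CoreParams:
    """The reference parameter set: N=1e9, mu=1e-9, r=1, omega=0.1, D=0.1."""
    return CoreParams.stable(r=1.0, mu=1e-9, N=1e9, omega=0.1, D=0.1)


def mc_branching_extinction(*, s: float, D: float, r: float = 1.0,
                            tau: float | None = None,
                            first_duration: float | None = None,
                            n_rep: int = 100_000, seed: int = 0,
                            size_cap: int = 500, max_cycles: int = 400
                            ) -> tuple[float, float]:
    """Monte-Carlo eventual-extinction frequency of a one-cell mutant
    lineage under growth-phase + binomial-bottleneck cycles.

    ``first_duration`` shortens the lineage's first growth phase (a
    mutation arising mid-phase); afterwards full phases of ``tau`` apply.
    A lineage is deemed safe once it exceeds ``size_cap`` cells at a phase
    start.  Returns (extinction frequency, its standard error).
    """
    if tau is None:
        tau = math.log(1.0 / D) / r
    rng = np.random.default_rng(seed)
    rate = r * (1.0 + s)
    sizes = np.ones(n_rep, dtype=np.int64)

    def grow(sz: np.ndarray, duration: float) -> np.ndarray:
        p = math.exp(-rate * duration)
        out = sz.copy()
        alive = sz > 0
        out[alive] += rng.negative_binomial(sz[alive], p)
        return out

    sizes = grow(sizes, tau if first_duration is None else first_duration)
    sizes = rng.binomial(sizes, D)
    for _ in range(max_cycles):
        undecided = (sizes > 0) & (sizes <= size_cap)
        if not undecided.any():
            break
        grown = grow(sizes[undecided], tau)
        sizes[undecided] = rng.binomial(grown, D)
    extinct = float(np.mean(sizes == 0))
    se = math.sqrt(max(extinct * (1.0 - extinct), 1e-12) / n_rep)
    return extinct, se


def mc_yule_event_driven(*, rate: float, elapsed: float, n_rep: int,
                         seed: int = 0) -> np.ndarray:
    """Sizes of ``n_rep`` pure-birth processes simulated division by
    division (every waiting time an explicit exponential draw)."""
    rng = np.random.default_rng(seed)
    n = np.ones(n_rep, dtype=np.int64)
    t = rng.exponential(1.0 / (rate * n))
    active = t < elapsed
    while active.any():
        n[active] += 1
        t[active] += rng.exponential(1.0 / (rate * n[active]))
        active = t < elapsed
    return n
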