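"""Closed-form theory: growth laws, survival probabilities, rates, optima."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import special, stats

from evopassage import (
    CoreParams,
    MutationContext,
    bottleneck_rate_factor,
    bottleneck_transition_pmf,
    continuous_culture_rate,
    fixation_rate_approx,
    fixation_rate_exact,
    fixation_rate_general,
    ne_effective,
    optimal_D_fixed_tau,
    survival_at_time,
    survival_initial,
    yule_size_pmf,
)

from conftest import mc_branching_extinction, mc_yule_event_driven


def bottleneck_pmf_bruteforce(beta: float, D: float, i: int,
                              j_max: int = 2000) -> float:
    """Oracle: explicit truncated double sum over the pre-bottleneck count."""
    j = np.arange(max(i, 1), j_max)
    geom = beta * (1.0 - beta) ** (j - 1)
    binom = special.comb(j, i) * D ** i * (1.0 - D) ** (j - i)
    return float(np.sum(geom * binom))


class TestYuleSizeLaw:
    @pytest.mark.parametrize("u,j,expected", [
        (0.0, 1, 1.0),            # no time elapsed: exactly one cell
        (math.log(2), 1, 0.5),    # beta = 1/2
        (math.log(2), 2, 0.25),
    ])
    def test_geometric_values(self, u, j, expected):
        assert yule_size_pmf(1.0, u, j) == pytest.approx(expected, abs=1e-12)

    def test_normalizes(self):
        total = np.sum(yule_size_pmf(1.0, 1.0, np.arange(1, 2001)))
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_matches_event_driven_simulation(self):
        """Per-cell exponential division times reproduce the geometric law."""
        sizes = mc_yule_event_driven(rate=1.0, elapsed=1.0, n_rep=100_000, seed=7)
        kmax = 30
        counts = np.bincount(np.minimum(sizes, kmax + 1), minlength=kmax + 2)[1:]
        pmf = yule_size_pmf(1.0, 1.0, np.arange(1, kmax + 1))
        expected = np.append(pmf, 1.0 - pmf.sum()) * len(sizes)
        chi2 = stats.chisquare(counts, expected)
        assert chi2.pvalue > 0.01

    def test_rejects_outside_support(self):
        with pytest.raises(ValueError):
            yule_size_pmf(1.0, 1.0, 0)
        with pytest.raises(ValueError):
            yule_size_pmf(1.0, -0.5, 1)


class TestBottleneckTransition:
    def test_zero_survivors_closed_form(self):
        # P0 = beta(1-D) / (1 - (1-beta)(1-D)) = 0.25/0.75
        assert bottleneck_transition_pmf(0.5, 0.5, 0) == pytest.approx(1 / 3, abs=1e-12)

    @pytest.mark.parametrize("i", range(6))
    def test_matches_truncated_double_sum(self, i):
        for beta, D in [(0.5, 0.5), (0.2, 0.3), (0.8, 0.9), (0.05, 0.1)]:
            closed = bottleneck_transition_pmf(beta, D, i)
            brute = bottleneck_pmf_bruteforce(beta, D, i)
            assert closed == pytest.approx(brute, rel=1e-9, abs=1e-12)

    def test_single_cell_degenerate(self):
        """beta -> 1: one cell faces the bottleneck, a bare Bernoulli(D)."""
        D = 0.37
        assert bottleneck_transition_pmf(1.0, D, 0) == pytest.approx(1 - D)
        assert bottleneck_transition_pmf(1.0, D, 1) == pytest.approx(D)
        assert bottleneck_transition_pmf(1.0, D, 5) == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(beta=st.floats(0.01, 0.99), D=st.floats(0.01, 0.99))
    def test_normalization_and_mean(self, beta, D):
        """Sum 1 and mean D/beta (thinning preserves the mean)."""
        i = np.arange(0, 3000)
        pmf = bottleneck_transition_pmf(beta, D, i)
        assert float(np.sum(pmf)) == pytest.approx(1.0, abs=1e-9)
        assert float(np.sum(i * pmf)) == pytest.approx(D / beta, rel=1e-9)

    def test_rejects_negative_count(self):
        with pytest.raises(ValueError):
            bottleneck_transition_pmf(0.5, 0.5, -1)


class TestSurvivalProbabilities:
    def test_initial_closed_form(self):
        assert survival_initial(1.0, 0.5) == pytest.approx(1 / 3, rel=1e-12)

    def test_neutral_lineage_dies(self):
        for D in (0.01, 0.5, 0.99):
            assert survival_initial(0.0, D) == 1.0

    def test_continuous_culture_limit_is_birth_death(self):
        """D -> 1 recovers the classic 1/(1+s) extinction probability."""
        assert survival_initial(0.5, 1 - 1e-9) == pytest.approx(2 / 3, rel=1e-6)

    def test_initial_matches_branching_simulation(self):
        freq, se = mc_branching_extinction(s=1.0, D=0.5, n_rep=100_000, seed=11)
        assert abs(freq - 1 / 3) < 3 * se

    def test_boundary_t_zero(self):
        for s, D in [(0.3, 0.1), (1.0, 0.5), (0.05, 0.8)]:
            tau = math.log(1 / D)
            ctx = MutationContext.at(s=s, t=0.0, r=1.0, tau=tau)
            assert survival_at_time(ctx, D) == pytest.approx(
                survival_initial(s, D), rel=1e-12)

    def test_boundary_t_near_tau(self):
        """A mutation just before the bottleneck: survive it (prob D) and
        then face V(0, s), else extinct."""
        s, D = 0.4, 0.2
        tau = math.log(1 / D)
        ctx = MutationContext.at(s=s, t=tau * (1 - 1e-12), r=1.0, tau=tau)
        expected = (1 - D) + D * survival_initial(s, D)
        assert survival_at_time(ctx, D) == pytest.approx(expected, abs=1e-9)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(data=st.data())
    def test_compound_identity(self, data):
        """The closed form equals the pgf of the first-bottleneck transition
        evaluated at the fixed point V(0, s)."""
        D = data.draw(st.floats(0.02, 0.95))
        s = data.draw(st.floats(0.01, 2.0))
        tau = math.log(1 / D)
        t = data.draw(st.floats(0.0, tau * 0.999))
        ctx = MutationContext.at(s=s, t=t, r=1.0, tau=tau)
        v0 = survival_initial(s, D)
        i = np.arange(0, 4000)
        pgf_at_v0 = float(np.sum(bottleneck_transition_pmf(ctx, D, i) * v0 ** i))
        assert survival_at_time(ctx, D) == pytest.approx(pgf_at_v0, abs=1e-9)

    def test_mid_phase_matches_branching_simulation(self):
        """r=1, tau=ln 10, D=0.1, s=0.1, t=1: the closed form against an
        independent branching Monte-Carlo."""
        D, s, t, tau = 0.1, 0.1, 1.0, math.log(10)
        ctx = MutationContext.at(s=s, t=t, r=1.0, tau=tau)
        v = survival_at_time(ctx, D)
        freq, se = mc_branching_extinction(
            s=s, D=D, first_duration=tau - t, n_rep=100_000, seed=13)
        assert abs(freq - v) < 3 * se

    def test_rejects_bad_domain(self):
        with pytest.raises(ValueError):
            survival_initial(1.0, 1.5)
        with pytest.raises(ValueError):
            MutationContext.at(s=0.1, t=3.0, r=1.0, tau=2.0)


class TestAdaptationRate:
    def test_zero_mutation_rate(self):
        p = CoreParams.stable(D=0.1, mu=0.0)
        assert fixation_rate_exact(p).gamma == 0.0

    def test_approx_reference_values(self, core_d01):
        # D -> 1 limit: 0.1/1.1 per hour; D = 0.1: x ln(10)/9
        lim = continuous_culture_rate(r=1, mu=1e-9, N=1e9, omega=0.1)
        assert lim == pytest.approx(0.0909091, rel=1e-5)
        assert fixation_rate_approx(core_d01).gamma == pytest.approx(
            0.0909091 * math.log(10) / 9, rel=1e-5)

    def test_continuous_vs_hundredfold_ratio(self):
        """The D -> 1 rate exceeds conventional 100:1 passaging ~21.5-fold."""
        ratio = 1.0 / bottleneck_rate_factor(0.01)
        assert ratio == pytest.approx(99 / math.log(100), rel=1e-12)
        assert 10.0 < ratio < 100.0

    def test_approx_tracks_exact_with_known_effect_size_bias(self):
        """The closed form replaces E[s/(1+s)] by omega/(1+omega); the
        resulting relative error is derivable from the exponential integral
        and the exact double integral must match it away from small D
        (for large omega the factorization needs larger D to set in)."""
        for omega, d_values in ((0.01, (0.1, 0.5, 0.9)), (0.1, (0.1, 0.5, 0.9)),
                                (1.0, (0.5, 0.9))):
            x = 1.0 / omega
            mean_s_frac = 1.0 - x * math.exp(x) * special.exp1(x)  # E[s/(1+s)]
            predicted = (omega / (1.0 + omega)) / mean_s_frac
            for D in d_values:
                p = CoreParams.stable(D=D, omega=omega)
                observed = fixation_rate_approx(p).gamma / fixation_rate_exact(p).gamma
                assert observed == pytest.approx(predicted, rel=0.012)

    def test_approx_within_two_percent_at_small_omega(self):
        for D in (0.001, 0.01, 0.1, 0.5, 0.9, 0.999):
            p = CoreParams.stable(D=D, omega=0.01)
            ex = fixation_rate_exact(p).gamma
            assert abs(fixation_rate_approx(p).gamma - ex) / ex < 0.02

    def test_monotone_increasing_in_D(self):
        for omega in (0.01, 0.1, 1.0):
            d = np.linspace(0.001, 0.999, 200)
            g = [fixation_rate_approx(CoreParams.stable(D=x, omega=omega)).gamma
                 for x in d]
            assert np.all(np.diff(g) > 0)

    def test_limit_factor(self):
        assert bottleneck_rate_factor(1.0) == 1.0
        assert bottleneck_rate_factor(1 - 1e-12) == pytest.approx(1.0, abs=1e-9)

    def test_gamma_over_D_nearly_proportional(self):
        """gamma/D varies by less than a factor 3 across D in [0.1, 0.999]."""
        d = np.linspace(0.1, 0.999, 100)
        ratio = [bottleneck_rate_factor(x) / x for x in d]
        assert max(ratio) / min(ratio) < 3.0


class TestEffectiveSizeAndGeneralRate:
    def test_reference_value(self):
        p = CoreParams.stable(D=0.1)
        assert ne_effective(p) == pytest.approx(1e9 * math.log(10) / 18, rel=1e-9)

    def test_limit_is_half_N(self):
        """As printed, N_e -> N r / 2 as D -> 1 (not N, as sometimes
        expected: a persistent factor-2 gap in the closed form)."""
        p = CoreParams.stable(D=1 - 1e-10)
        assert ne_effective(p) == pytest.approx(p.N * p.r / 2, rel=1e-6)
        assert not math.isclose(ne_effective(p), p.N, rel_tol=0.4)

    def test_definitional_consistency(self, core_d01):
        """N_e * mu * 2 omega equals the rate up to the dropped (1+omega)."""
        lhs = ne_effective(core_d01) * core_d01.mu * 2 * core_d01.omega
        rhs = fixation_rate_approx(core_d01).gamma
        assert lhs / rhs == pytest.approx(1 + core_d01.omega, rel=1e-9)

    def test_general_rate_reduces_to_exponential_case(self, core_d01):
        g = fixation_rate_general(tau=math.log(10), mu=1e-9, N_star=1e9,
                                  omega=0.1, D=0.1).gamma
        assert g == pytest.approx(fixation_rate_approx(core_d01).gamma, rel=1e-12)

    def test_fixed_tau_peak_beats_e_minus_2(self):
        g = lambda d: fixation_rate_general(tau=24, mu=1e-9, N_star=1e9,
                                            omega=0.1, D=d).gamma
        assert g(0.203) > g(math.exp(-2))


class TestOptimalDilution:
    def test_fixed_tau_optimum(self):
        d, ratio = optimal_D_fixed_tau(24.0)
        assert d == pytest.approx(0.2032, abs=5e-4)
        assert ratio == pytest.approx(4.92, abs=0.01)
        # the optimum is the root of 2(e^x - 1) = x e^x
        x = -math.log(d)
        assert 2 * math.expm1(x) == pytest.approx(x * math.exp(x), rel=1e-8)

    def test_independent_of_tau(self):
        assert optimal_D_fixed_tau(1.0).D == pytest.approx(
            optimal_D_fixed_tau(24.0).D, abs=1e-6)

    def test_matches_brute_force_grid(self):
        y = np.linspace(math.log(1e-6), math.log(1 - 1e-6), 100_000)
        x = -y
        vals = x * x / np.expm1(x)
        d_grid = math.exp(y[int(np.argmax(vals))])
        assert abs(optimal_D_fixed_tau().D - d_grid) < 1e-4

    def test_rejects_bad_tau(self):
        with pytest.raises(ValueError):
            optimal_D_fixed_tau(-1.0)


class TestParamValidation:
    def test_core_params_domain(self):
        with pytest.raises(ValueError):
            CoreParams(r=1, mu=1e-9, N=1e9, omega=0.1, D=1.0, tau=1.0)
        with pytest.raises(ValueError):
            CoreParams(r=-1, mu=1e-9, N=1e9, omega=0.1, D=0.5, tau=1.0)

    def test_stability_constraint_enforced(self):
        p = CoreParams(r=1, mu=1e-9, N=1e9, omega=0.1, D=0.5, tau=3.0)
        with pytest.raises(ValueError):
            fixation_rate_exact(p)
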