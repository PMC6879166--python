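"""Unit tests for discretisations, priors, the SMC' kernel and modulation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import integrate, stats

import rhosmc as r
from rhosmc.errors import InvalidArgumentError

LN2 = np.log(2.0)


class TestTimeDiscretization:
    def test_single_interval_is_prior_mean(self):
        d = r.build_time_discretization(1)
        assert d.boundaries[0] == 0 and np.isinf(d.boundaries[1])
        assert d.representative[0] == pytest.approx(1.0)

    def test_two_intervals_closed_form(self):
        # median of Exp(1) at ln 2; conditional means 1 -/+ ln 2
        d = r.build_time_discretization(2)
        assert d.boundaries[1] == pytest.approx(LN2, abs=1e-12)
        assert d.representative == pytest.approx([1 - LN2, 1 + LN2], abs=1e-12)

    @pytest.mark.parametrize("t", [1, 3, 17, 40])
    def test_masses_partition_prior(self, t):
        d = r.build_time_discretization(t)
        assert d.masses.sum() == pytest.approx(1.0, abs=1e-12)
        assert d.masses == pytest.approx(np.full(t, 1 / t), abs=1e-12)
        assert np.all(np.diff(d.boundaries[:-1]) > 0)
        # representatives interior to their interval
        assert np.all(d.representative > d.boundaries[:-1])
        assert np.all(d.representative[:-1] < d.boundaries[1:-1])

    def test_invalid_t(self):
        with pytest.raises(InvalidArgumentError):
            r.build_time_discretization(0)

    def test_nonconstant_demography_shifts_boundaries(self):
        fast = r.Demography.piecewise([0.01], [1.0, 20.0])
        d = r.build_time_discretization(8, fast)
        d0 = r.build_time_discretization(8)
        assert d.boundaries[4] < d0.boundaries[4]  # faster ancient coalescence


class TestRhoCategories:
    def test_k1_any_alpha(self):
        assert r.build_rho_categories(3.7, 1) == pytest.approx([1.0])

    def test_exponential_closed_form(self):
        assert r.build_rho_categories(1.0, 2) == pytest.approx(
            [1 - LN2, 1 + LN2], abs=1e-10)

    @pytest.mark.parametrize("alpha,k", [(0.5, 5), (5.0, 4), (0.1, 3)])
    def test_matches_quadrature_oracle(self, alpha, k):
        edges = np.concatenate([
            [0.0], stats.gamma.ppf(np.arange(1, k) / k, a=alpha,
                                   scale=1 / alpha), [np.inf]])
        oracle = []
        for lo, hi in zip(edges[:-1], edges[1:]):
            val, _ = integrate.quad(
                lambda x: x * stats.gamma.pdf(x, a=alpha, scale=1 / alpha),
                lo, min(hi, stats.gamma.ppf(1 - 1e-14, a=alpha,
                                            scale=1 / alpha)))
            oracle.append(val * k)
        assert r.build_rho_categories(alpha, k) == pytest.approx(
            oracle, abs=1e-6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(alpha=st.floats(0.05, 20.0), k=st.integers(1, 12))
    def test_mean_one_and_increasing(self, alpha, k):
        means = r.build_rho_categories(alpha, k)
        assert abs(means.mean() - 1.0) < 1e-8
        assert np.all(np.diff(means) > 0) or k == 1

    def test_invalid_alpha(self):
        with pytest.raises(InvalidArgumentError):
            r.build_rho_categories(0.0, 4)


class TestRhoTransition:
    def test_no_switching_is_identity(self):
        assert np.array_equal(r.build_rho_transition(0.0, 4), np.eye(4))

    def test_printed_form(self):
        assert r.build_rho_transition(0.1, 2) == pytest.approx(
            np.array([[0.9, 0.1], [0.1, 0.9]]))
        q = r.build_rho_transition(0.000025, 10)
        off = q[~np.eye(10, dtype=bool)]
        assert off == pytest.approx(0.000025 / 9)

    def test_invalid_delta(self):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(InvalidArgumentError):
                r.build_rho_transition(bad, 3)


class TestSmcTransition:
    def test_zero_rho_is_exact_identity(self, disc5):
        assert np.array_equal(
            r.smc_transition_matrix(disc5, None, 0.0), np.eye(5))

    @pytest.mark.parametrize("rho", [1e-5, 1e-3, 1e-2])
    def test_rows_stochastic(self, disc5, rho):
        q = r.smc_transition_matrix(disc5, None, rho)
        assert np.abs(q.sum(axis=1) - 1).max() < 1e-10
        assert q.min() >= 0 and q.max() <= 1

    def test_off_diagonal_mass_monotone_in_rho(self, disc5):
        grid = [1e-5, 1e-4, 1e-3, 5e-3]
        masses = [1 - np.diag(r.smc_transition_matrix(disc5, None, rho)).min()
                  for rho in grid]
        assert np.all(np.diff(masses) > 0)

    @pytest.mark.parametrize("t,rho", [(5, 1.2e-3), (20, 1.2e-3),
                                       (40, 1.5e-4)])
    def test_prior_is_stationary(self, t, rho):
        """Exact integration over the source interval makes the discretised
        TMRCA prior the stationary law of the kernel (model-regime rho)."""
        d = r.build_time_discretization(t)
        q = r.smc_transition_matrix(d, None, rho)
        w, v = np.linalg.eig(q.T)
        pi = np.real(v[:, np.argmax(np.real(w))])
        pi /= pi.sum()
        assert np.abs(pi - d.masses).max() < 1e-6

    def test_nonconstant_demography_stationarity(self):
        dem = r.Demography.piecewise([0.5], [1.0, 0.05])
        d = r.build_time_discretization(8, dem)
        q = r.smc_transition_matrix(d, dem, 1e-3)
        assert np.abs(d.masses @ q - d.masses).max() < 1e-6


class TestMonteCarloOracle:
    def test_single_step_sampler_agrees(self, disc5):
        """SMC' matrix rows vs a 1e6-draw single-step simulation under the
        constant rate-1 coalescent."""
        rho = 1e-3
        q = r.smc_transition_matrix(disc5, None, rho)
        rng = np.random.default_rng(123)
        n = 1_000_000
        b = disc5.boundaries
        for i in range(disc5.t):
            # s ~ conditional prior inside interval i (Exp(1) truncated)
            lo, hi = b[i], b[i + 1]
            u01 = rng.random(n)
            cdf_lo, cdf_hi = 1 - np.exp(-lo), 1 - np.exp(-min(hi, 1e9))
            s = -np.log1p(-(cdf_lo + u01 * (cdf_hi - cdf_lo)))
            new = s.copy()
            rec = rng.random(n) < -np.expm1(-rho * s)
            idx = np.flatnonzero(rec)
            u = rng.random(idx.size) * s[idx]
            # phase 1: two partners on (u, s)
            w1 = u + rng.exponential(0.5, idx.size)
            below = w1 < s[idx]
            back = rng.random(idx.size) < 0.5
            new_i = np.where(below, np.where(back, s[idx], w1),
                             s[idx] + rng.exponential(1.0, idx.size))
            new[idx] = new_i
            counts = np.array([np.mean((new >= b[j]) & (new < b[j + 1]))
                               for j in range(disc5.t)])
            se = np.sqrt(np.maximum(counts * (1 - counts), 1e-12) / n)
            assert np.all(np.abs(counts - q[i]) <= 3 * se + 1e-9), \
                f"row {i}: {counts} vs {q[i]}"


class TestModulate:
    def test_k1_degenerate(self, disc5):
        q = r.smc_transition_matrix(disc5, None, 1e-3)
        assert np.array_equal(r.modulate([q], np.array([[1.0]])), q)

    def test_block_arithmetic(self):
        a = np.array([[0.7, 0.3], [0.2, 0.8]])
        b = np.array([[0.5, 0.5], [0.4, 0.6]])
        p = np.array([[0.9, 0.1], [0.25, 0.75]])
        q = r.modulate([a, b], p)
        assert q[0:2, 0:2] == pytest.approx(0.9 * a)
        assert q[0:2, 2:4] == pytest.approx(0.1 * a)
        assert q[2:4, 0:2] == pytest.approx(0.25 * b)
        assert q[2:4, 2:4] == pytest.approx(0.75 * b)
        assert np.abs(q.sum(axis=1) - 1).max() < 1e-10

    def test_delta_zero_block_diagonal(self, disc5):
        prior = r.build_rho_prior(0.5, 3, 0.0, 1e-3)
        kern = r.build_kernel(prior, disc5)
        q = kern.q_composite
        t = disc5.t
        off = q.copy()
        for l in range(3):
            off[l * t:(l + 1) * t, l * t:(l + 1) * t] = 0
        assert np.abs(off).max() == 0

    def test_dimension_mismatch(self):
        with pytest.raises(InvalidArgumentError):
            r.modulate([np.eye(2), np.eye(3)], np.eye(2))

    def test_state_budget_enforced(self):
        disc = r.build_time_discretization(41)
        prior = r.build_rho_prior(0.5, 5, 1e-5, 1e-3)
        with pytest.raises(InvalidArgumentError):
            r.build_kernel(prior, disc)


class TestEmissions:
    def test_closed_form_and_monotonicity(self, disc5):
        e = r.emission_matrix(r.MutationModel(0.003), disc5)
        assert np.all(np.diff(e[:, 1]) > 0)  # increasing in tree height
        assert np.allclose(e[:, 0] + e[:, 1], 1.0)
        assert np.all(e[:, 2] == 1.0)
        d1 = r.build_time_discretization(1)
        e1 = r.emission_matrix(r.MutationModel(0.003), d1)
        assert e1[0, 1] == pytest.approx(1 - np.exp(-0.003), rel=1e-12)

    def test_vanishing_theta(self, disc5):
        e = r.emission_matrix(r.MutationModel(1e-12), disc5)
        assert e[:, 1] == pytest.approx(0.0, abs=1e-10)


class TestSplineDemography:
    def test_constant_knots_give_constant_rate(self):
        dem = r.Demography.from_spline(np.full(5, 0.7))
        d = r.build_time_discretization(12, dem)
        assert r.spline_lambdas(dem, d) == pytest.approx(np.exp(0.7))

    def test_parameter_count_independent_of_t(self):
        obs = r.ObservedSequence(
            np.array([0, 1, 0, 0, 1, 0, 0, 0, 1, 0] * 30, dtype=np.uint8))
        f20 = r.fit(obs, 4, 1, maxiter=0)
        f40 = r.fit(obs, 8, 1, maxiter=0)
        assert f20.n_params == f40.n_params

    def test_monotone_knots_monotone_lambdas(self):
        dem = r.Demography.from_spline(np.array([-1.0, -0.5, 0.0, 0.5, 1.0]))
        d = r.build_time_discretization(10, dem)
        lam = r.spline_lambdas(dem, d)
        assert np.all(np.diff(lam) >= -1e-12)
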