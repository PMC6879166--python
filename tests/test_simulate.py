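"""Statistical checks on the synthetic-data generators."""

import numpy as np
import pytest
from scipy import integrate, stats

import rhosmc as r


class TestRhoLandscape:
    def test_study_scale_statistics(self):
        """alpha=0.5, g=100 kb on a long sequence: unit mean scale and the
        nominal mean segment length, each within 3 SE."""
        land = r.gen_rho_landscape(0.5, 100_000, 30_000_000, 0.0012, seed=3)
        n = land.n_segments
        # per-segment scales: Gamma(0.5, rate 0.5), sd = sqrt(2)
        se_scale = np.sqrt(2.0 / n)
        assert abs(land.scales.mean() - 1.0) <= 3 * se_scale
        # geometric lengths, sd ~ g
        se_len = 100_000 / np.sqrt(n)
        assert abs(land.lengths[:-1].mean() - 100_000) <= 3 * se_len

    def test_single_segment_when_g_exceeds_L(self):
        land = r.gen_rho_landscape(1.0, 10_000_000, 1000, 0.001, seed=0)
        assert land.n_segments == 1
        assert land.per_site().shape == (1000,)

    def test_deterministic_given_seed(self):
        a = r.gen_rho_landscape(0.5, 1000, 50_000, 0.0012, seed=9)
        b = r.gen_rho_landscape(0.5, 1000, 50_000, 0.0012, seed=9)
        assert np.array_equal(a.scales, b.scales)
        assert np.array_equal(a.lengths, b.lengths)


class TestThetaLandscape:
    def test_expected_genome_wide_theta(self):
        """Uniform(0.1, 10) scales have mean 5.05, so theta0 = 0.003 gives
        an expected genome-wide average of 0.01515."""
        land = r.gen_theta_landscape(20_000, 10_000_000, 0.003, seed=4)
        assert np.all((land.scales >= 0.1) & (land.scales <= 10.0))
        per_site = land.per_site()
        se = 0.003 * np.std(land.scales) / np.sqrt(land.n_segments)
        assert abs(per_site.mean() - 0.01515) <= 4 * se

    def test_segment_count(self):
        land = r.gen_theta_landscape(20_000, 30_000_000, 0.003, seed=5)
        expect = 30_000_000 / 20_000
        assert abs(land.n_segments - expect) <= 3 * np.sqrt(expect)


@pytest.fixture(scope="module")
def small_model():
    disc = r.build_time_discretization(4)
    prior = r.build_rho_prior(0.5, 3, 2e-3, 0.01)
    kernel = r.build_kernel(prior, disc)
    emissions = r.emission_matrix(r.MutationModel(0.1), disc)
    return prior, kernel, emissions


class TestHmmPathSimulator:
    def test_no_switching_when_delta_zero(self):
        disc = r.build_time_discretization(3)
        prior = r.build_rho_prior(0.5, 4, 0.0, 1e-3)
        kernel = r.build_kernel(prior, disc)
        emissions = r.emission_matrix(r.MutationModel(0.01), disc)
        truth = r.simulate_hmm_path(kernel, emissions, 5000, seed=1,
                                    category_rates=prior.category_means)
        assert len(np.unique(truth.rho)) == 1

    def test_transition_frequencies(self, small_model):
        _, kernel, emissions = small_model
        L = 1_000_000
        truth = r.simulate_hmm_path(kernel, emissions, L, seed=2)
        from rhosmc._kernels import sample_hmm_path
        states, _ = sample_hmm_path(np.cumsum(kernel.q_composite, axis=1),
                                    np.tile(emissions[:, 1], kernel.k),
                                    np.cumsum(kernel.stationary), L, 2)
        # empirical one-step frequencies vs the kernel, 3 SE per cell
        n = kernel.n
        counts = np.zeros((n, n))
        np.add.at(counts, (states[:-1], states[1:]), 1)
        row_n = counts.sum(axis=1, keepdims=True)
        freq = counts / np.maximum(row_n, 1)
        se = np.sqrt(kernel.q_composite * (1 - kernel.q_composite)
                     / np.maximum(row_n, 1))
        ok = row_n[:, 0] > 1000
        assert np.all(np.abs(freq[ok] - kernel.q_composite[ok])
                      <= 3 * se[ok] + 1e-4)

    def test_het_fraction_moment(self, small_model):
        _, kernel, emissions = small_model
        L = 500_000
        truth = r.simulate_hmm_path(kernel, emissions, L, seed=3)
        expect = float(kernel.stationary @ np.tile(emissions[:, 1], kernel.k))
        se = np.sqrt(expect * (1 - expect) / L)
        # positive autocorrelation inflates the naive SE; allow a margin
        assert abs(truth.obs.codes.mean() - expect) <= 10 * se


class TestSequentialSimulator:
    def test_no_recombination_single_tmrca(self):
        land = r.Landscape(starts=np.array([0]), lengths=np.array([10_000]),
                           scales=np.array([1.0]), base_rate=0.0, L=10_000,
                           seed=0)
        truth = r.simulate_sequential_smc(land, None, None, 0.01, seed=6)
        assert len(np.unique(truth.tmrca)) == 1

    def test_mean_tmrca_constant_demography(self):
        """Homogeneous rho, constant coalescent: site-averaged TMRCA is 1,
        checked against the empirical SE of independent replicates."""
        n_rep = 10
        means = []
        for i in range(n_rep):
            land = r.Landscape(starts=np.array([0]),
                               lengths=np.array([1_000_000]),
                               scales=np.array([1.0]), base_rate=0.0012,
                               L=1_000_000, seed=0)
            truth = r.simulate_sequential_smc(land, None, None, 0.003,
                                              seed=700 + i)
            means.append(float(truth.tmrca.mean()))
        means = np.asarray(means)
        se = means.std(ddof=1) / np.sqrt(n_rep)
        assert abs(means.mean() - 1.0) <= 3 * se

    def test_het_fraction_matches_prior_expectation(self):
        theta = 0.003
        land = r.gen_rho_landscape(0.5, 100_000, 5_000_000, 0.0012, seed=9)
        truth = r.simulate_sequential_smc(land, None, None, theta, seed=10)
        expect, _ = integrate.quad(
            lambda s: (1 - np.exp(-theta * s)) * np.exp(-s), 0, 50)
        n_eff = len(np.unique(truth.tmrca))
        se = np.sqrt(expect / n_eff)  # tree-level, not site-level, noise
        assert abs(truth.obs.codes.mean() - expect) <= 4 * se

    def test_marginal_tmrca_distribution(self):
        """First-site TMRCA across independent replicates follows the
        demography's prior (KS test)."""
        dem = r.Demography.piecewise([0.5], [1.0, 0.05])
        land = r.Landscape(starts=np.array([0]), lengths=np.array([2]),
                           scales=np.array([1.0]), base_rate=0.001, L=2,
                           seed=0)
        draws = np.array([
            r.simulate_sequential_smc(land, None, dem, 0.003,
                                      seed=100 + i).tmrca[0]
            for i in range(2000)])

        def cdf(x):
            x = np.asarray(x)
            h = np.where(x < 0.5, x, 0.5 + 0.05 * (x - 0.5))
            return 1 - np.exp(-h)

        assert stats.kstest(draws, cdf).pvalue > 0.01

    def test_changepoint_count_scales_with_rho(self):
        counts = []
        for rho in (2e-4, 2e-3):
            land = r.Landscape(starts=np.array([0]),
                               lengths=np.array([2_000_000]),
                               scales=np.array([1.0]), base_rate=rho,
                               L=2_000_000, seed=0)
            truth = r.simulate_sequential_smc(land, None, None, 0.003,
                                              seed=11)
            counts.append(np.sum(np.diff(truth.tmrca) != 0))
        ratio = counts[1] / counts[0]
        assert 7 < ratio < 14  # ~linear in rho over a 10x range

    def test_theta_landscape_modulates_heterozygosity(self):
        land = r.gen_rho_landscape(0.5, 100_000, 2_000_000, 0.0012, seed=12)
        th = r.gen_theta_landscape(20_000, 2_000_000, 0.003, seed=13)
        truth = r.simulate_sequential_smc(land, th, None, seed=14)
        het = truth.obs.codes == 1
        hi = th.per_site() > 0.015
        assert het[hi].mean() > 2 * het[~hi].mean()


class TestLoopClosure:
    def test_map_accuracy_increases_with_theta_rho_ratio(self):
        """Full pipeline on the generator's own output: inferred maps
        explain variance (R^2 > 0), and more mutations per recombination
        (higher theta/rho) give better maps."""
        scores = {}
        for ratio, theta in ((0.5, 0.0006), (2.5, 0.003)):
            vals = []
            for rep in range(3):
                land = r.gen_rho_landscape(0.5, 100_000, 1_000_000, 0.0012,
                                           seed=900 + rep)
                truth = r.simulate_sequential_smc(land, None, None, theta,
                                                  seed=910 + rep)
                hom = r.fit(truth.obs, 10, 1, maxiter=3)
                het = r.fit(truth.obs, 10, 5, init=hom, maxiter=3,
                            refit_demography=False)
                field = r.decode(truth.obs, het)
                rmap = r.posterior_mean_rho(field, het.prior)
                vals.append(r.compare_r2(
                    r.bin_map(rmap, 50_000),
                    r.bin_values(land.per_site(), 50_000),
                    n_bootstrap=10).r2)
            scores[ratio] = float(np.mean(vals))
        assert scores[2.5] > 0
        assert scores[2.5] > scores[0.5]


class TestStructuredPair:
    def test_introgression_pair_basics(self):
        land = r.gen_rho_landscape(0.5, 100_000, 400_000, 0.0012, seed=15)
        truth = r.simulate_structured_pair(land, pulse_time=0.25, seed=16)
        codes = truth.obs.codes
        assert len(codes) == 400_000
        h = codes.mean()
        # pairwise diversity close to theta-scale (split inflates deep trees)
        assert 0.001 < h < 0.01


class TestMissingData:
    def test_target_fraction_and_determinism(self):
        obs = r.ObservedSequence(np.zeros(100_000, dtype=np.uint8))
        m1 = r.apply_missing(obs, 0.3, seed=1)
        m2 = r.apply_missing(obs, 0.3, seed=1)
        frac = np.mean(m1.codes == 2)
        assert 0.29 <= frac <= 0.35
        assert np.array_equal(m1.codes, m2.codes)
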