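import numpy as np
import pytest

from wfgp import gp_likelihood as gp
from wfgp import synthetic_data as sd


@pytest.fixture(scope="module")
def perfect_ld_panel():
    hap = np.array([[1, 1], [1, 1], [0, 0], [0, 0]])
    return sd.FounderPanel(hap, [100, 900], 1_000)


class TestInitialState:
    def test_perfect_ld_c0(self, perfect_ld_panel):
        init = gp.initial_state_from_founders(perfect_ld_panel, [0, 1])
        assert init.pair_c0(0, 1) == pytest.approx(0.25)
        np.testing.assert_allclose(init.haplotype_freqs([0, 1]), [0.5, 0, 0, 0.5])

    def test_independent_loci_zero_c0(self):
        hap = np.array([[1, 1], [1, 0], [0, 1], [0, 0]])
        panel = sd.FounderPanel(hap, [10, 20], 100)
        init = gp.initial_state_from_founders(panel, [0, 1])
        assert init.pair_c0(0, 1) == pytest.approx(0.0)

    def test_tabulation_identities(self, small_panel):
        init = gp.initial_state_from_founders(small_panel, [0, 3, 7])
        z8 = init.haplotype_freqs([0, 3, 7])
        assert z8.sum() == pytest.approx(1.0)
        from wfgp.selected_moments import marginal_matrix

        np.testing.assert_allclose(
            marginal_matrix(3) @ z8, small_panel.frequencies[[0, 3, 7]]
        )

    def test_selected_must_be_in_loci(self, small_panel):
        with pytest.raises(ValueError):
            gp.initial_state_from_founders(small_panel, [0, 1], selected=5)


class TestRecombinationFraction:
    def test_zero_distance(self):
        theta = gp.ModelTheta(N_e=100, r_per_bp=1e-8)
        assert gp.recombination_fraction(500, 500, theta) == 0.0

    def test_linear_regime(self):
        theta = gp.ModelTheta(N_e=100, r_per_bp=1e-8)
        assert gp.recombination_fraction(1, 10_001, theta) == pytest.approx(1e-4)

    def test_hotspot_additivity(self):
        theta = gp.ModelTheta(
            N_e=100, r_per_bp=1e-8, hotspot=(49_000, 51_000, 1_000.0)
        )
        val = gp.recombination_fraction(40_000, 60_000, theta)
        background = 1e-8 * 20_000
        hotspot_extra = (1_000 - 1) * 1e-8 * 2_000
        assert val == pytest.approx(background + hotspot_extra)

    def test_capped_at_half(self):
        theta = gp.ModelTheta(N_e=100, r_per_bp=1e-3)
        assert gp.recombination_fraction(0, 10_000, theta) == 0.5


class TestBuildGaussian:
    def test_neutral_means_are_martingale(self, small_panel, default_design):
        theta = gp.ModelTheta(N_e=1000, r_per_bp=2e-8)
        init = gp.initial_state_from_founders(small_panel, [0, 5, 10])
        ga = gp.build_gaussian(theta, default_design, init)
        T = len(default_design.sampling_generations)
        for j, locus in enumerate(ga.loci):
            np.testing.assert_allclose(
                ga.mean[j * T : (j + 1) * T], small_panel.frequencies[locus], atol=1e-6
            )

    def test_replicates_iid_block_structure(self, small_panel):
        """The joint likelihood over R=2 replicates equals the sum of two
        single-replicate likelihoods with the same block (block-diagonal
        covariance with equal blocks)."""
        d2 = sd.ExperimentDesign(N=500, sampling_generations=(10, 20), R=2)
        d1 = sd.ExperimentDesign(N=500, sampling_generations=(10, 20), R=1)
        theta = gp.ModelTheta(N_e=500, s=0.1, h=0.5)
        sel = int(np.argmin(np.abs(small_panel.frequencies - 0.5)))
        init = gp.initial_state_from_founders(small_panel, [sel], selected=sel)
        ga2 = gp.build_gaussian(theta, d2, init)
        ga1 = gp.build_gaussian(theta, d1, init)
        np.testing.assert_array_equal(ga1.cov, ga2.cov)
        res = sd.run_experiment(small_panel, d2, sd.SelectionConfig(sel, 0.1, 0.5), seed=4)
        freqs = res.data.frequencies[:, [sel], :]
        ll2 = gp.log_likelihood(sd.TrajectoryData(frequencies=freqs), ga2)
        parts = [
            gp.log_likelihood(sd.TrajectoryData(frequencies=freqs[:, :, [k]]), ga1)
            for k in range(2)
        ]
        assert ll2 == pytest.approx(sum(parts))

    def test_covariance_psd_and_symmetric(self, small_panel, default_design):
        theta = gp.ModelTheta(N_e=1000, s=0.1, h=0.5, r_per_bp=2e-8)
        sel = 5
        init = gp.initial_state_from_founders(
            small_panel, [2, 5, 9, 14], selected=sel
        )
        ga = gp.build_gaussian(theta, default_design, init)
        np.testing.assert_allclose(ga.cov, ga.cov.T)
        assert np.linalg.eigvalsh(ga.cov).min() > -1e-10

    def test_moments_match_forward_simulation(self):
        """Grid means/covariances under selection within Monte-Carlo error
        of forward E&R simulations (moderate N keeps the check cheap)."""
        panel = sd.generate_founder_panel(20, 5_000, 40, rng_seed=1)
        design = sd.ExperimentDesign(N=300, sampling_generations=(10, 25), R=1)
        freqs = panel.frequencies
        sel = int(np.argmin(np.abs(freqs - 0.4)))
        other = int(np.argmin(np.abs(freqs - 0.6) + (np.arange(40) == sel)))
        loci = sorted([sel, other], key=lambda j: panel.positions[j])
        # HWE-randomized start isolates the moment approximation from the
        # homozygous-founder first generation
        pop0 = sd.clone_founders(panel, 300)
        rng = np.random.default_rng(0)
        n_mc = 2_000
        out = np.empty((n_mc, 2, 2))
        selcfg = sd.SelectionConfig(sel, 0.1, 0.5)
        for i in range(n_mc):
            shuffled = pop0[rng.permutation(600)]
            out[i] = sd.evolve_population(shuffled, design, selcfg, rng, panel.positions)[
                :, loci
            ]
        theta = gp.ModelTheta(N_e=300, s=0.1, h=0.5, r_per_bp=2e-8)
        init = gp.initial_state_from_founders(panel, loci, selected=sel)
        ga = gp.build_gaussian(theta, design, init)
        flat_mc = out.transpose(0, 2, 1).reshape(n_mc, -1)
        se = flat_mc.std(axis=0) / np.sqrt(n_mc)
        z = (ga.mean - flat_mc.mean(axis=0)) / se
        assert np.abs(z).max() < 4.0
        mc_var = flat_mc.var(axis=0)
        np.testing.assert_allclose(np.diag(ga.cov), mc_var, rtol=0.2)


class TestLogLikelihood:
    def test_density_at_mean(self, small_panel, default_design):
        theta = gp.ModelTheta(N_e=1000)
        init = gp.initial_state_from_founders(small_panel, [1, 4])
        ga = gp.build_gaussian(theta, default_design, init)
        T, K, R = len(ga.times), len(ga.loci), default_design.R
        freqs = ga.mean.reshape(K, T).T[:, :, None] * np.ones((1, 1, R))
        ll = gp.log_likelihood(sd.TrajectoryData(frequencies=freqs), ga)
        n = K * T
        sign, logdet = np.linalg.slogdet(ga.cov)
        expected = R * (-0.5 * (n * np.log(2 * np.pi) + logdet))
        assert ll == pytest.approx(expected, abs=1e-4)

    def test_quadrature_degenerate_is_binomial_pmf(self):
        from scipy.stats import binom

        val = gp.log_likelihood_quadrature_1d(5, 10, 0.5, 0.0)
        assert val == pytest.approx(np.log(binom.pmf(5, 10, 0.5)))
        assert np.exp(val) == pytest.approx(0.24609375)

    def test_gaussian_emission_close_to_quadrature(self):
        """Single-observation Gaussian emission within 0.05 nats of the
        exact marginal evaluated by adaptive quadrature."""
        d, c, mu, var = 5, 10, 0.5, 0.01
        ga = gp.GaussianApprox(
            mean=np.array([mu]), cov=np.array([[var]]),
            loci=(0,), times=(10,), R=1, N_e=1000,
        )
        data = sd.TrajectoryData(
            frequencies=np.array([[[d / c]]]),
            counts=np.array([[[d]]]),
            coverages=np.array([[[c]]]),
        )
        approx = gp.log_likelihood(data, ga)
        exact = gp.log_likelihood_quadrature_1d(d, c, mu, var)
        assert abs(approx - exact) < 0.05

    def test_zero_coverage_dropped(self):
        ga = gp.GaussianApprox(
            mean=np.array([0.5, 0.5]), cov=0.01 * np.eye(2),
            loci=(0,), times=(10, 20), R=1, N_e=100,
        )
        full = sd.TrajectoryData(
            frequencies=np.array([[[0.5]], [[0.5]]]),
            counts=np.array([[[5]], [[5]]]),
            coverages=np.array([[[10]], [[10]]]),
        )
        partial = sd.TrajectoryData(
            frequencies=np.array([[[0.5]], [[np.nan]]]),
            counts=np.array([[[5]], [[0]]]),
            coverages=np.array([[[10]], [[0]]]),
        )
        ll_full = gp.log_likelihood(full, ga)
        ll_partial = gp.log_likelihood(partial, ga)
        assert np.isfinite(ll_partial)
        assert ll_partial > ll_full  # one fewer observation in the product

    def test_inflating_covariance_lowers_density_at_mean(self, small_panel, default_design):
        theta = gp.ModelTheta(N_e=1000)
        init = gp.initial_state_from_founders(small_panel, [1])
        ga = gp.build_gaussian(theta, default_design, init)
        T = len(ga.times)
        freqs = ga.mean.reshape(1, T).T[:, :, None] * np.ones((1, 1, default_design.R))
        data = sd.TrajectoryData(frequencies=freqs)
        ll = gp.log_likelihood(data, ga)
        inflated = gp.GaussianApprox(
            mean=ga.mean, cov=4 * ga.cov, loci=ga.loci, times=ga.times,
            R=ga.R, N_e=ga.N_e,
        )
        assert gp.log_likelihood(data, inflated) < ll

    def test_allele_relabeling_invariance(self, default_design):
        """Flipping A0/A1 at every locus and mapping
        (s, h) -> (-s/(1+s), 1-h) leaves the likelihood unchanged."""
        panel = sd.generate_founder_panel(20, 5_000, 30, rng_seed=9)
        sel = int(np.argmin(np.abs(panel.frequencies - 0.4)))
        loci = sorted({sel, 3, 20})
        s, h = 0.15, 0.7
        res = sd.run_experiment(panel, default_design, sd.SelectionConfig(sel, s, h), seed=2)
        cols = np.array(sorted(loci, key=lambda j: panel.positions[j]))
        data = sd.TrajectoryData(frequencies=res.data.frequencies[:, cols, :])
        theta = gp.ModelTheta(N_e=1000, s=s, h=h, r_per_bp=2e-8)
        init = gp.initial_state_from_founders(panel, list(cols), selected=sel)
        ll = gp.log_likelihood(data, gp.build_gaussian(theta, default_design, init))

        flipped_panel = sd.FounderPanel(
            1 - panel.haplotypes, panel.positions, panel.region_length
        )
        flipped_data = sd.TrajectoryData(frequencies=1 - data.frequencies)
        s2, h2 = -s / (1 + s), 1 - h
        theta2 = gp.ModelTheta(N_e=1000, s=s2, h=h2, r_per_bp=2e-8)
        init2 = gp.initial_state_from_founders(flipped_panel, list(cols), selected=sel)
        ll2 = gp.log_likelihood(flipped_data, gp.build_gaussian(theta2, default_design, init2))
        assert ll2 == pytest.approx(ll, abs=1e-5)

    def test_neutral_model_preferred_on_neutral_data(self, small_panel, default_design):
        """Average log-likelihood of the true neutral model exceeds that of
        a fixed s = 0.1 model on neutral simulations."""
        site = int(np.argmin(np.abs(small_panel.frequencies - 0.5)))
        init = gp.initial_state_from_founders(small_panel, [site], selected=site)
        ga0 = gp.build_gaussian(gp.ModelTheta(N_e=1000), default_design,
                                gp.initial_state_from_founders(small_panel, [site]))
        gas = gp.build_gaussian(
            gp.ModelTheta(N_e=1000, s=0.1, h=0.5), default_design, init
        )
        diffs = []
        for seed in range(15):
            res = sd.run_experiment(small_panel, default_design, seed=seed)
            data = sd.TrajectoryData(frequencies=res.data.frequencies[:, [site], :])
            diffs.append(gp.log_likelihood(data, ga0) - gp.log_likelihood(data, gas))
        assert np.mean(diffs) > 0
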