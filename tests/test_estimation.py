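"""Bound-constrained rate estimation, uncertainty and diagnostics."""

import numpy as np
import pytest

from ppdkin import (
    ConcentrationProfile,
    ExperimentDesign,
    FitConfig,
    NoiseSpec,
    UnderdeterminedError,
    correlation_matrix,
    fit,
    generate_dataset,
    hpd_interval,
    simulate,
    sum_squared_residuals,
)


@pytest.fixture(scope="module")
def clean_dataset(network, k_ref, c0_pure_a, grid_10):
    return simulate(network, k_ref, c0_pure_a, grid_10)


@pytest.fixture(scope="module")
def clean_fit(clean_dataset, network):
    return fit(clean_dataset, network)


class TestSumSquaredResiduals:
    def test_perfect_fit_is_zero(self, clean_dataset, network, k_ref):
        assert sum_squared_residuals(clean_dataset, network, k_ref) < 1e-18

    def test_single_cell_offset(self, clean_dataset, network, k_ref):
        delta = 3e-4
        conc = clean_dataset.conc.copy()
        conc[4, 2] += delta
        bumped = ConcentrationProfile(
            times=clean_dataset.times, conc=conc, species=clean_dataset.species
        )
        assert sum_squared_residuals(bumped, network, k_ref) == pytest.approx(
            delta**2, rel=1e-10
        )

    def test_noise_variance_recovered(self, network, k_ref, c0_pure_a):
        # law of large numbers: ssr / n -> sigma^2 over ~10^4 cells
        sigma = 0.01
        times = np.linspace(0.0, 360.0, 1112)
        design = ExperimentDesign(times=times, c0=c0_pure_a, k_true=k_ref)
        noisy = generate_dataset(
            design, NoiseSpec(kind="additive_gaussian", sigma=sigma, seed=7, clip_negative=False)
        )
        ssr = sum_squared_residuals(noisy, network, k_ref, c0=c0_pure_a)
        n = noisy.conc.size
        assert ssr / n == pytest.approx(sigma**2, rel=0.05)


class TestFit:
    def test_noiseless_recovery_of_reference_constants(self, clean_fit, k_ref):
        nonzero = k_ref > 0
        rel = np.abs(clean_fit.estimates[nonzero] - k_ref[nonzero]) / k_ref[nonzero]
        assert rel.max() < 1e-3
        assert clean_fit.converged

    def test_zero_constants_land_on_bound(self, clean_fit):
        assert clean_fit.at_bound[7] and clean_fit.at_bound[8]
        assert clean_fit.estimates[7] == 0.0 and clean_fit.estimates[8] == 0.0
        assert np.isnan(clean_fit.hpd95[7]) and np.isnan(clean_fit.hpd95[8])

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_crime_on_random_rates(self, network, c0_pure_a, grid_10, seed):
        rng = np.random.default_rng(seed)
        k_true = rng.uniform(5e-4, 8e-3, size=12)
        data = simulate(network, k_true, c0_pure_a, grid_10)
        result = fit(data, network)
        assert np.abs(result.estimates - k_true).max() / k_true.min() < 1e-4

    def test_single_zero_generating_constant_hits_bound(
        self, network, c0_pure_a, grid_10, k_ref
    ):
        k_true = k_ref.copy()
        k_true[7] = k_true[8] = 1e-3  # free the usual suspects
        k_true[4] = 0.0
        data = simulate(network, k_true, c0_pure_a, grid_10)
        result = fit(data, network)
        assert result.at_bound[4]

    def test_underdetermined_single_row(self, network, c0_pure_a):
        one_row = ConcentrationProfile(
            times=np.array([0.0]), conc=c0_pure_a[None, :], species=tuple("ABCDEFGHI")
        )
        with pytest.raises(UnderdeterminedError):
            fit(one_row, network)

    def test_underdetermined_single_species_column(self, clean_dataset, network):
        conc = np.full_like(clean_dataset.conc, np.nan)
        conc[:, 0] = clean_dataset.conc[:, 0]
        sparse = ConcentrationProfile(
            times=clean_dataset.times, conc=conc, species=clean_dataset.species
        )
        with pytest.raises(UnderdeterminedError):
            fit(sparse, network, c0=clean_dataset.conc[0])

    def test_scale_invariance(self, clean_dataset, network, clean_fit):
        alpha = 7.25
        scaled = ConcentrationProfile(
            times=clean_dataset.times,
            conc=alpha * clean_dataset.conc,
            species=clean_dataset.species,
        )
        result = fit(scaled, network)
        assert np.allclose(result.estimates, clean_fit.estimates, rtol=1e-6, atol=1e-12)

    def test_monotone_information_with_denser_sampling(self, network, k_ref, c0_pure_a):
        config = FitConfig(obs_sigma=0.02)
        widths = {}
        for n in (10, 19):  # 19-point grid nests the 10-point grid
            times = np.linspace(0.0, 360.0, n)
            data = simulate(network, k_ref, c0_pure_a, times)
            widths[n] = fit(data, network, config).hpd95
        free = np.isfinite(widths[10]) & np.isfinite(widths[19])
        assert np.all(widths[19][free] <= widths[10][free] + 1e-12)


class TestCorrelation:
    def test_diagonal_and_symmetry(self, network, k_ref, c0_pure_a, grid_10):
        data = generate_dataset(
            ExperimentDesign(times=grid_10, c0=c0_pure_a, k_true=k_ref),
            NoiseSpec(sigma=0.02, seed=11),
        )
        result = fit(data, network, c0=c0_pure_a)
        corr = correlation_matrix(result)
        free = result.free
        sub = corr[np.ix_(free, free)]
        assert np.allclose(np.diag(sub), 1.0)
        assert np.allclose(sub, sub.T, atol=1e-12)
        off = sub[~np.eye(sub.shape[0], dtype=bool)]
        assert np.all(np.abs(off) <= 1.0 + 1e-12)

    def test_at_bound_rows_unavailable(self, clean_fit):
        corr = correlation_matrix(clean_fit)
        assert np.all(np.isnan(corr[7, :])) and np.all(np.isnan(corr[:, 8]))


class TestHpdInterval:
    def test_gaussian_half_width(self):
        rng = np.random.default_rng(5)
        lo, hi = hpd_interval(rng.standard_normal(200_000))
        assert (hi - lo) / 2 == pytest.approx(1.959964, abs=0.02)

    def test_matches_arviz_on_skewed_samples(self):
        arviz = pytest.importorskip("arviz")
        rng = np.random.default_rng(9)
        samples = rng.gamma(2.0, 1.0, size=100_000)
        lo, hi = hpd_interval(samples, level=0.9)
        ref = arviz.hdi(samples, hdi_prob=0.9)
        assert lo[0] == pytest.approx(ref[0], abs=0.02)
        assert hi[0] == pytest.approx(ref[1], abs=0.02)

    @pytest.mark.parametrize("level", [0.0, 1.0, -0.5])
    def test_degenerate_level_rejected(self, level):
        with pytest.raises(ValueError, match="level"):
            hpd_interval(np.zeros(500), level=level)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="100"):
            hpd_interval(np.zeros(50))


@pytest.fixture(scope="module")
def mcmc_config():
    return FitConfig(
        uncertainty_method="mcmc",
        weighting="relative",
        mcmc_walkers=32,
        mcmc_burn=400,
        mcmc_draws=300,
        seed=4,
    )


@pytest.fixture(scope="module")
def noisy_dataset(network, k_ref, c0_pure_a, grid_10):
    return generate_dataset(
        ExperimentDesign(times=grid_10, c0=c0_pure_a, k_true=k_ref),
        NoiseSpec(sigma=0.02, seed=21),
    )


class TestMcmc:
    def test_posterior_hpd_consistent_with_laplace(
        self, noisy_dataset, network, c0_pure_a, mcmc_config
    ):
        mcmc_res = fit(noisy_dataset, network, mcmc_config, c0=c0_pure_a)
        laplace_res = fit(
            noisy_dataset, network, FitConfig(weighting="relative"), c0=c0_pure_a
        )
        # compare only constants far from the bound: truncation at zero makes
        # the posterior of weakly identified constants genuinely non-Gaussian
        both = (
            mcmc_res.free
            & laplace_res.free
            & (laplace_res.estimates > 2 * np.nan_to_num(laplace_res.hpd95, nan=np.inf))
        )
        assert both.sum() >= 6
        ratio = mcmc_res.hpd95[both] / laplace_res.hpd95[both]
        assert np.all(ratio > 0.5) and np.all(ratio < 2.0), ratio
        assert mcmc_res.samples is not None and mcmc_res.samples.shape[1] == 12

    def test_seeded_sampler_is_reproducible(
        self, noisy_dataset, network, c0_pure_a, mcmc_config
    ):
        a = fit(noisy_dataset, network, mcmc_config, c0=c0_pure_a)
        b = fit(noisy_dataset, network, mcmc_config, c0=c0_pure_a)
        assert np.array_equal(a.samples, b.samples)
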