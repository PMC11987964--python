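"""Generative models: closed forms, likelihoods, MCMC, and samplers."""

import numpy as np
import pytest
from scipy import integrate, stats

from centrospat import (
    DEFAULT_REGION,
    InvalidParameterError,
    MCMCConfig,
    ModelFitResult,
    NucleusRegion,
    PriorSpec,
    RadialGaussianModel,
    RadialGaussianParams,
    analytic_radial_k,
    centered_pairwise_cdf,
    fit_ellipse_to_mask,
    fit_m3,
    fit_m4,
    generate_from_model,
    log_posterior,
    metropolis_hastings,
    pairwise_distance_pdf_mc,
    pairwise_loglik,
    radial_loglik,
    region_from_mask,
    sample_centered_radial_gaussian,
    sample_m2,
    sample_radially_shifted_gaussian,
)


class TestAnalyticRadialK:
    def test_zero_at_origin_and_half_point(self):
        assert analytic_radial_k(0.0, sigma=5.0) == 0.0
        r_half = 5.0 * np.sqrt(2 * np.log(2))
        assert analytic_radial_k(r_half, sigma=5.0) == pytest.approx(0.5)

    def test_matches_quadrature_of_radial_integral(self):
        # closed form vs direct quadrature of the polar-coordinate integral
        sigma = 7.0
        for r in np.linspace(0.1, 5 * sigma, 20):
            num, _ = integrate.quad(
                lambda rho: rho / sigma**2 * np.exp(-(rho**2) / (2 * sigma**2)), 0, r
            )
            assert analytic_radial_k(r, sigma) == pytest.approx(num, abs=1e-8)

    def test_monotone_and_saturating(self):
        r = np.linspace(0, 50, 100)
        k = analytic_radial_k(r, sigma=6.0, c=2.0, lam=0.5)
        assert (np.diff(k) > 0).all()
        assert k[-1] == pytest.approx(4.0, rel=1e-6)


class TestRadialLoglik:
    def test_concentrated_data_value(self):
        n, sigma = 7, 3.0
        assert radial_loglik([5.0] * n, 5.0, sigma) == pytest.approx(
            -n / 2 * np.log(2 * np.pi * sigma**2)
        )

    def test_hand_value(self):
        assert radial_loglik([1, 2, 3], 2.0, 1.0) == pytest.approx(-3.757, abs=5e-4)

    def test_maximized_at_sample_mean(self):
        radii = np.array([2.0, 4.0, 9.0, 5.0])
        grid = np.linspace(0, 10, 1001)
        vals = [radial_loglik(radii, r0, 1.7) for r0 in grid]
        assert grid[np.argmax(vals)] == pytest.approx(radii.mean(), abs=0.02)

    def test_nonpositive_sigma_is_minus_inf(self):
        assert radial_loglik([1.0], 1.0, 0.0) == -np.inf


class TestLogPosterior:
    def test_zero_data_map_at_prior_means(self):
        prior = PriorSpec(20.0, 25.0, 5.0, 4.0)
        grid_r0 = np.linspace(10, 30, 401)
        vals = [log_posterior([], r0, 5.0, prior) for r0 in grid_r0]
        assert grid_r0[np.argmax(vals)] == pytest.approx(20.0, abs=0.05)

    def test_quadratic_form_matches_compact_exponent(self):
        # difference of two log posteriors equals the printed -1/2 [...] form
        prior = PriorSpec(20.0, 25.0, 5.0, 4.0)
        radii = np.array([18.0, 22.0, 25.0])

        def quad(r0, s):
            return -0.5 * (
                np.sum((radii - r0) ** 2) / s**2
                + (r0 - 20.0) ** 2 / 25.0
                + (s - 5.0) ** 2 / 4.0
            )

        for (r0a, sa), (r0b, sb) in [((19, 4.0), (23, 6.0)), ((15, 5.0), (25, 5.0))]:
            got = log_posterior(radii, r0a, sa, prior) - log_posterior(radii, r0b, sb, prior)
            # the sigma-dependent normalization -n log sigma is part of the
            # likelihood but not of the compact exponent
            norm = -len(radii) * (np.log(sa) - np.log(sb))
            assert got == pytest.approx(quad(r0a, sa) - quad(r0b, sb) + norm)

    def test_conjugate_normal_posterior_mean(self):
        # fixed sigma, Normal prior on r0: the MH chain must match the
        # closed-form precision-weighted posterior
        rng = np.random.default_rng(0)
        sigma, mu0, tau2 = 4.0, 10.0, 9.0
        radii = rng.normal(14.0, sigma, 60)
        post_prec = 1 / tau2 + len(radii) / sigma**2
        post_mean = (mu0 / tau2 + radii.sum() / sigma**2) / post_prec
        post_sd = np.sqrt(1 / post_prec)

        def lp(x):
            return radial_loglik(radii, x[0], sigma) - 0.5 * (x[0] - mu0) ** 2 / tau2

        cfg = MCMCConfig(n_iter=8000, burn_in=1000, seed=2)
        res = metropolis_hastings(lp, [mu0], cfg, param_names=("r0",))
        n_eff = len(res.draws) / 10  # generous autocorrelation allowance
        assert res.draws.mean() == pytest.approx(post_mean, abs=3 * post_sd / np.sqrt(n_eff))
        assert res.draws.std(ddof=1) == pytest.approx(post_sd, rel=0.25)


class TestMetropolisHastings:
    def test_chain_length_and_acceptance(self):
        cfg = MCMCConfig(n_iter=500, burn_in=100, seed=0)
        res = metropolis_hastings(lambda x: -0.5 * x[0] ** 2, [0.0], cfg, steps=[1.0])
        assert len(res.draws) == 400
        assert 0.0 < res.acceptance_rate < 1.0

    def test_uphill_proposals_always_accepted(self):
        # on a monotone target every proposal toward higher posterior sticks
        seen = []

        def lp(x):
            seen.append(x[0])
            return x[0]

        cfg = MCMCConfig(n_iter=300, burn_in=0, seed=1)
        res = metropolis_hastings(lp, [0.0], cfg, steps=[0.5])
        improving = np.diff(res.log_posterior) > 0
        assert improving.any()  # sanity: the chain does move uphill

    def test_infinite_init_rejected(self):
        with pytest.raises(InvalidParameterError):
            metropolis_hastings(
                lambda x: -np.inf, [0.0], MCMCConfig(n_iter=10, burn_in=0), steps=[1.0]
            )


class TestPairwisePdfMc:
    def test_unit_mass(self):
        edges, dens = pairwise_distance_pdf_mc(
            RadialGaussianParams(20.0, 5.0), n_mc=20_000, seed=0
        )
        width = edges[1] - edges[0]
        assert dens.sum() * width == pytest.approx(1.0)

    def test_small_sigma_concentrates_below_2r0(self):
        edges, dens = pairwise_distance_pdf_mc(
            RadialGaussianParams(20.0, 0.5), n_mc=20_000, seed=0
        )
        centers = 0.5 * (edges[1:] + edges[:-1])
        mass_above = dens[centers > 2 * 20.0 + 3].sum() * (edges[1] - edges[0])
        assert mass_above < 1e-3

    def test_loglik_floor_for_off_grid_distances(self):
        edges, dens = pairwise_distance_pdf_mc(
            RadialGaussianParams(10.0, 1.0), n_mc=20_000, seed=0
        )
        val = pairwise_loglik([1e6, 2e6], edges, dens)
        assert val == pytest.approx(2 * -1e10)

    def test_likelihood_prefers_generating_parameters(self):
        rng = np.random.default_rng(3)
        true = RadialGaussianParams(25.0, 6.0)
        r1 = true.r0 + true.sigma * rng.standard_normal(4000)
        r2 = true.r0 + true.sigma * rng.standard_normal(4000)
        ok = (r1 >= 0) & (r2 >= 0)
        d = np.sqrt(
            r1[ok] ** 2 + r2[ok] ** 2
            - 2 * r1[ok] * r2[ok] * np.cos(rng.uniform(0, 2 * np.pi, ok.sum()))
        )
        e_true, p_true = pairwise_distance_pdf_mc(true, n_mc=50_000, seed=1)
        shifted = RadialGaussianParams(35.0, 6.0)
        e_shift, p_shift = pairwise_distance_pdf_mc(shifted, n_mc=50_000, seed=1)
        assert pairwise_loglik(d, e_true, p_true) > pairwise_loglik(d, e_shift, p_shift)


class TestEllipseFitting:
    @staticmethod
    def _ellipse_mask(a, b, angle, shape=(200, 200)):
        yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
        cx, cy = shape[1] / 2, shape[0] / 2
        c, s = np.cos(angle), np.sin(angle)
        u = c * (xx - cx) + s * (yy - cy)
        v = -s * (xx - cx) + c * (yy - cy)
        return (u / a) ** 2 + (v / b) ** 2 <= 1.0

    def test_disk_recovers_radius(self):
        m = self._ellipse_mask(50, 50, 0.0)
        _, a, b, _ = fit_ellipse_to_mask(m)
        assert a == pytest.approx(50, rel=0.02)
        assert b == pytest.approx(50, rel=0.02)

    def test_rotated_ellipse_recovered(self):
        ang = np.deg2rad(30)
        m = self._ellipse_mask(60, 30, ang)
        center, a, b, got = fit_ellipse_to_mask(m)
        assert a == pytest.approx(60, rel=0.02)
        assert b == pytest.approx(30, rel=0.02)
        assert got == pytest.approx(ang, abs=0.05)
        assert center[0] == pytest.approx(100, abs=1)

    def test_quarter_turn_swaps_axes(self):
        m1 = self._ellipse_mask(60, 30, 0.0)
        m2 = self._ellipse_mask(60, 30, np.pi / 2)
        _, a1, b1, ang1 = fit_ellipse_to_mask(m1)
        _, a2, b2, ang2 = fit_ellipse_to_mask(m2)
        assert a1 == pytest.approx(a2, rel=0.02)
        assert abs(ang1 - ang2) == pytest.approx(np.pi / 2, abs=0.05)

    def test_degenerate_mask_rejected(self):
        m = np.zeros((10, 10), bool)
        m[5, 5] = True
        with pytest.raises(InvalidParameterError):
            fit_ellipse_to_mask(m)


class TestM2Sampler:
    def test_axis_spreads_and_containment(self):
        m = TestEllipseFitting._ellipse_mask(60, 30, 0.0, shape=(220, 220))
        region = region_from_mask(m)
        p = sample_m2(region, 20000, seed=0)
        centered = p.spots - np.asarray(region.center)
        assert abs(centered.mean(axis=0)).max() < 0.7
        # truncation trims the tails a little; 10% band on a/3 and b/3
        assert centered[:, 0].std() == pytest.approx(60 / 3, rel=0.10)
        assert centered[:, 1].std() == pytest.approx(30 / 3, rel=0.10)
        assert region.contains(p.spots).all()


class TestM3:
    def test_closed_form_landmark(self):
        assert centered_pairwise_cdf(2 * 9.0, 9.0) == pytest.approx(1 - np.e**-1)

    def test_sampler_matches_analytic_pairwise_cdf(self):
        # the centered Gaussian sampler and its closed-form pairwise CDF
        region = NucleusRegion(center=(0.0, 0.0), radius=200.0)
        p = sample_centered_radial_gaussian(10.0, region, 700, seed=0)
        from scipy.spatial.distance import pdist

        d = pdist(p.spots)
        ks = stats.kstest(d, lambda x: centered_pairwise_cdf(x, 10.0)).statistic
        assert ks < 0.02

    def test_sigma_recovery(self):
        region = NucleusRegion(center=(0.0, 0.0), radius=300.0)
        from scipy.spatial.distance import pdist

        rng = np.random.default_rng(5)
        cells = [
            pdist(sample_centered_radial_gaussian(10.0, region, 300, rng).spots)
            for _ in range(4)
        ]
        res = fit_m3(cells)
        assert 9.5 <= res.sigma <= 10.5
        assert "sigma" in res.summary()


class TestDoughnutSampler:
    def test_concentration_and_containment(self):
        params = RadialGaussianParams(30.0, 0.8)
        p = sample_radially_shifted_gaussian(params, DEFAULT_REGION, 20000, seed=0)
        r = np.linalg.norm(p.spots - np.array(DEFAULT_REGION.center), axis=1)
        assert r.mean() == pytest.approx(30.0, rel=0.02)
        assert DEFAULT_REGION.contains(p.spots).all()

    def test_radial_histogram_peaks_near_r0(self):
        params = RadialGaussianParams(30.0, 5.0)
        p = sample_radially_shifted_gaussian(params, DEFAULT_REGION, 100_000, seed=1)
        r = np.linalg.norm(p.spots - np.array(DEFAULT_REGION.center), axis=1)
        counts, edges = np.histogram(r, bins=40, range=(0, 46))
        mode = 0.5 * (edges[:-1] + edges[1:])[np.argmax(counts)]
        assert mode == pytest.approx(30.0, abs=3.0)


class TestM4:
    def test_parameter_recovery_normalized_pooling(self):
        rng = np.random.default_rng(7)
        true = RadialGaussianParams(30.0, 8.0)
        cells, radii = [], []
        for _ in range(100):
            p = sample_radially_shifted_gaussian(true, DEFAULT_REGION, 46, rng)
            cells.append(np.linalg.norm(p.spots - np.array(DEFAULT_REGION.center), axis=1))
            radii.append(DEFAULT_REGION.radius)
        res = fit_m4(cells, radii, mcmc=MCMCConfig(n_iter=4000, burn_in=1000, seed=0))
        assert res.r0 * 46.0 == pytest.approx(30.0, rel=0.05)
        assert res.sigma * 46.0 == pytest.approx(8.0, rel=0.12)
        assert 0.05 < res.acceptance_rate < 0.8
        assert "r0" in res.summary()

    def test_posterior_sd_shrinks_with_more_cells(self):
        rng = np.random.default_rng(8)
        true = RadialGaussianParams(30.0, 8.0)

        def fit_n(n_cells, seed):
            cells = []
            for _ in range(n_cells):
                p = sample_radially_shifted_gaussian(true, DEFAULT_REGION, 46, rng)
                cells.append(
                    np.linalg.norm(p.spots - np.array(DEFAULT_REGION.center), axis=1)
                )
            return fit_m4(cells, mcmc=MCMCConfig(n_iter=3000, burn_in=800, seed=seed))

        small = fit_n(8, 1)
        big = fit_n(120, 2)
        assert big.bse[0] < small.bse[0]

    def test_no_data_posterior_follows_prior(self):
        prior = PriorSpec(20.0, 4.0, 5.0, 1.0)
        model = RadialGaussianModel([[]], prior=prior)
        res = model.fit(MCMCConfig(n_iter=6000, burn_in=1000, seed=3))
        assert res.r0 == pytest.approx(20.0, abs=3 * 2.0 / np.sqrt(50))
        assert res.sigma == pytest.approx(5.0, abs=3 * 1.0 / np.sqrt(50))


class TestGenerateFromModel:
    def test_m1_counts_and_determinism(self):
        fit = ModelFitResult("M1")
        nuclei = [DEFAULT_REGION] * 4
        a = generate_from_model(fit, nuclei, [10, 20, 30, 46], seed=5)
        b = generate_from_model(fit, nuclei, [10, 20, 30, 46], seed=5)
        assert [p.n_spots for p in a] == [10, 20, 30, 46]
        for pa, pb in zip(a, b):
            np.testing.assert_array_equal(pa.spots, pb.spots)

    def test_m4_params_rescaled_per_cell(self):
        fit = ModelFitResult("M4", params={"r0": 0.6, "sigma": 0.05}, normalized=True)
        big = NucleusRegion(center=(0.0, 0.0), radius=100.0)
        pats = generate_from_model(fit, [big], 5000, seed=6)
        r = np.linalg.norm(pats[0].spots, axis=1)
        assert r.mean() == pytest.approx(60.0, rel=0.03)
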