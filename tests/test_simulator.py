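"""Monte Carlo engine: spatial kernel, copula calibration, study simulation."""

import math

import numpy as np
import pytest
from scipy import integrate, stats
from scipy.stats import norm

from segpower import (
    ReferenceErrorModel,
    build_spatial_model,
    estimate_empirical_power,
    estimate_error_covariance,
    estimate_foreground_prob,
    generate_synthetic_pilot,
    masks_from_difference_field,
    sample_image_prior,
    sample_voxel_differences,
    simulate_images,
    simulate_study,
    voxel_differences,
)
from segpower.simulator import _calibrate_latent

from conftest import baseline_config


class TestSpatialModel:
    def test_kernel_values(self):
        sm = build_spatial_model((1, 2), 0.7)
        assert sm.corr[0, 0] == 1.0
        assert sm.corr[0, 1] == pytest.approx(math.exp(-1 / 0.49), abs=1e-9)
        assert sm.corr[0, 1] == pytest.approx(0.12992, abs=1e-5)

    def test_rho_bar_matches_brute_force_double_sum(self):
        sm = build_spatial_model((6, 6), 0.7)
        coords = [(i, j) for i in range(6) for j in range(6)]
        total = 0.0
        for yi, xi in coords:
            for yj, xj in coords:
                d = math.hypot(yi - yj, xi - xj)
                total += math.exp(-d / 0.49)
        assert sm.rho_bar == pytest.approx(total / 36**2, abs=1e-12)

    def test_zero_scale_gives_identity(self):
        sm = build_spatial_model((3, 3), 0.0)
        np.testing.assert_array_equal(sm.corr, np.eye(9))

    def test_scalar_voxel_count_requires_perfect_square(self):
        assert build_spatial_model(36, 0.7).grid_shape == (6, 6)
        with pytest.raises(ValueError, match="square"):
            build_spatial_model(35, 0.7)


class TestImagePrior:
    def test_moments_of_dirichlet_draws(self, rng):
        p = np.array([0.09, 0.85, 0.06])
        omega = 128.0
        draws = np.array([sample_image_prior(p, omega, rng) for _ in range(100_000)])
        se = draws.std(axis=0) / np.sqrt(len(draws))
        assert np.all(np.abs(draws.mean(axis=0) - p) < 3 * se)
        # variance of O1 - O-1 matches the Dirichlet moment identity
        diff = draws[:, 0] - draws[:, 2]
        psi, delta = p[0] + p[2], p[0] - p[2]
        expected = (psi - delta**2) / (omega + 1)
        observed = diff.var(ddof=1)
        se_var = observed * math.sqrt(2 / (len(draws) - 1))
        assert abs(observed - expected) < 3 * se_var

    def test_infinite_precision_returns_mean(self, rng):
        p = np.array([0.09, 0.85, 0.06])
        np.testing.assert_array_equal(sample_image_prior(p, math.inf, rng), p)

    def test_zero_component_stays_zero(self, rng):
        draw = sample_image_prior([0.3, 0.7, 0.0], 50.0, rng)
        assert draw[2] == 0.0 and abs(draw.sum() - 1) < 1e-12


class TestCopulaSampler:
    def test_marginals_recovered(self, rng):
        sm = build_spatial_model((1, 2), 0.7)
        o = np.array([0.09, 0.85, 0.06])
        draws = np.array([sample_voxel_differences(o, sm, rng) for _ in range(50_000)])
        for val, target in ((1, 0.09), (0, 0.85), (-1, 0.06)):
            prop = (draws == val).mean()
            se = math.sqrt(target * (1 - target) / draws.size)
            assert abs(prop - target) < 3 * se

    def test_pairwise_correlation_calibrated(self, rng):
        """Empirical ordinal correlation hits the kernel target within 0.02."""
        sm = build_spatial_model((1, 2), 0.7)  # two voxels, target 0.12989
        o = np.array([0.09, 0.85, 0.06])
        draws = np.array([sample_voxel_differences(o, sm, rng) for _ in range(100_000)])
        emp = np.corrcoef(draws[:, 0], draws[:, 1])[0, 1]
        assert abs(emp - sm.corr[0, 1]) < 0.02

    def test_calibration_against_brute_force_integration(self):
        """The calibrated latent correlation reproduces the target ordinal
        correlation when the thresholded bivariate normal is integrated
        directly (independent of the package's BVN routine)."""
        p1, pm1 = 0.09, 0.06
        p0 = 1 - p1 - pm1
        z1, z2 = norm.ppf(pm1), norm.ppf(pm1 + p0)
        target = 0.13
        r = float(_calibrate_latent(np.array([target]), z1, z2, p1, pm1)[0])

        def density(y, x):
            det = 1 - r * r
            return math.exp(-(x * x - 2 * r * x * y + y * y) / (2 * det)) / (
                2 * math.pi * math.sqrt(det)
            )

        def rect(x0, x1, y0, y1):
            val, _ = integrate.dblquad(density, x0, x1, y0, y1, epsabs=1e-10)
            return val

        lo, hi = -8.5, 8.5
        p_11 = rect(z2, hi, z2, hi)
        p_mm = rect(lo, z1, lo, z1)
        p_1m = rect(z2, hi, lo, z1)
        exy = p_11 + p_mm - 2 * p_1m
        ex = p1 - pm1
        var = (p1 + pm1) - ex * ex
        assert (exy - ex * ex) / var == pytest.approx(target, abs=2e-4)

    def test_identity_correlation_gives_independent_voxels(self, rng):
        sm = build_spatial_model((1, 2), 0.0)
        o = np.array([0.2, 0.6, 0.2])
        draws = np.array([sample_voxel_differences(o, sm, rng) for _ in range(20_000)])
        table = np.zeros((3, 3))
        for i, vi in enumerate((-1, 0, 1)):
            for j, vj in enumerate((-1, 0, 1)):
                table[i, j] = np.sum((draws[:, 0] == vi) & (draws[:, 1] == vj))
        _, p, _, _ = stats.chi2_contingency(table)
        assert p > 0.01

    def test_degenerate_marginal_gives_constant_field(self, rng):
        sm = build_spatial_model((2, 2), 0.7)
        assert np.all(sample_voxel_differences([0.0, 1.0, 0.0], sm, rng) == 0)
        assert np.all(sample_voxel_differences([1.0, 0.0, 0.0], sm, rng) == 1)

    def test_binomial_voxel_counts_without_correlation_or_prior(self, rng):
        """omega = inf and identity kernel: counts of D=1 are binomial(v, p1)."""
        sm = build_spatial_model((4, 4), 0.0)
        o = np.array([0.2, 0.7, 0.1])
        counts = np.array([
            (sample_voxel_differences(o, sm, rng) == 1).sum() for _ in range(4000)
        ])
        edges = [-0.5, 0.5, 1.5, 2.5, 3.5, 4.5, 16.5]
        observed = np.histogram(counts, bins=edges)[0]
        probs = np.diff([stats.binom.cdf(e, 16, 0.2) for e in edges])
        _, p = stats.chisquare(observed, probs / probs.sum() * len(counts))
        assert p > 0.01


class TestStudySimulation:
    def test_reproducible_for_fixed_seed(self, baseline_spatial):
        config = baseline_config(baseline_spatial, n_images=5, n_reps=20, seed=77)
        r1 = estimate_empirical_power(config)
        r2 = estimate_empirical_power(config)
        np.testing.assert_array_equal(r1.d_bar_samples, r2.d_bar_samples)
        assert r1.positives == r2.positives

    def test_realized_marginals_match_population(self, baseline_spatial):
        config = baseline_config(baseline_spatial, n_images=50, n_reps=20, seed=5)
        res = estimate_empirical_power(config)
        n_vox = 50 * 20 * baseline_spatial.v
        # images are the independent unit: SE of delta from per-image variance
        se_delta = math.sqrt(res.empirical_variance / (50 * 20))
        assert abs(res.empirical_delta - 0.03) < 3 * se_delta
        se_psi = math.sqrt(0.15 * 0.85 / n_vox) * 3  # conservative: ignores clustering
        assert abs(res.empirical_psi - 0.15) < 5 * se_psi

    def test_single_study_interface(self, baseline_spatial):
        config = baseline_config(baseline_spatial, n_images=8, seed=3)
        d_bar, sig = simulate_study(config)
        assert d_bar.shape == (8,)
        assert isinstance(sig, (bool, np.bool_))

    def test_type_one_error_calibrated_under_null(self, baseline_spatial):
        config = baseline_config(
            baseline_spatial, n_images=10, n_reps=800, seed=11, delta=0.0
        )
        res = estimate_empirical_power(config)
        se = math.sqrt(0.05 * 0.95 / 800)
        assert abs(res.empirical_power - 0.05) < 3 * se


class TestSyntheticPilot:
    TARGETS = dict(pa=0.246, pb=0.195, pl=0.210, ph=0.214, cov_ab_lh=-0.003)

    def test_masks_reproduce_difference_field(self, rng, baseline_spatial):
        config = baseline_config(baseline_spatial, n_images=6, seed=9)
        d, _, _ = simulate_images(config, 6, rng)
        l = rng.integers(0, 2, d.shape)
        for k in range(6):
            a, b = masks_from_difference_field(d[k], l[k])
            recon = np.abs(b - l[k]) - np.abs(a - l[k])
            np.testing.assert_array_equal(recon, d[k])

    def test_error_free_model_makes_H_equal_L(self, rng, baseline_spatial):
        config = baseline_config(baseline_spatial, n_images=10, seed=2)
        ref = ReferenceErrorModel.error_free(pa=0.25, pb=0.21, pl=0.22)
        pilot = generate_synthetic_pilot(config, ref, rng=rng)
        for l, h in zip(pilot.labels_L, pilot.labels_H):
            np.testing.assert_array_equal(l, h)

    def test_pooled_statistics_match_requests(self, baseline_spatial):
        config = baseline_config(baseline_spatial, n_images=600, seed=13)
        ref = ReferenceErrorModel(**self.TARGETS)
        pilot = generate_synthetic_pilot(config, ref)
        n_vox = 600 * baseline_spatial.v
        for attr, labels in (("pa", pilot.labels_A), ("pb", pilot.labels_B),
                             ("pl", pilot.labels_L), ("ph", pilot.labels_H)):
            target = self.TARGETS[attr]
            se = math.sqrt(target * (1 - target) / n_vox)
            # voxels within an image are correlated; widen by the design-ish factor
            assert abs(estimate_foreground_prob(labels) - target) < 9 * se
        cov_hat = estimate_error_covariance(pilot)
        se_cov = 3 / math.sqrt(n_vox)  # generous bound on the covariance SE
        assert abs(cov_hat - self.TARGETS["cov_ab_lh"]) < se_cov

    def test_infeasible_request_raises(self, baseline_spatial):
        config = baseline_config(baseline_spatial, n_images=5, seed=1)
        with pytest.raises(ValueError, match="infeasible"):
            generate_synthetic_pilot(
                config,
                ReferenceErrorModel(pa=0.246, pb=0.195, pl=0.21, ph=0.214, cov_ab_lh=-0.4),
            )
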