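"""Pilot-data estimators: pooled moments, variance bound, precision fit."""

import numpy as np
import pytest
from scipy import optimize, stats

from segpower import (
    EstimationConfig,
    SegpowerWarning,
    estimate_all,
    estimate_delta,
    estimate_design_factor,
    estimate_dirichlet_precision,
    estimate_error_covariance,
    estimate_foreground_prob,
    estimate_psi,
    estimate_rho_bar,
    estimate_variance,
    fit_dirichlet_multinomial_precision,
    variance_dirichlet,
    variance_upper_bound,
)
from segpower.estimation import OMEGA_CAP
from segpower.model import PilotDataset

from conftest import baseline_config
from test_model import make_pilot


class TestPooledMoments:
    def test_foreground_prob_pools_all_voxels(self):
        labels = (np.array([1, 0]), np.array([1, 1]))
        assert estimate_foreground_prob(labels) == 0.75
        assert estimate_foreground_prob((np.zeros(5, dtype=int),)) == 0.0
        with pytest.raises(ValueError):
            estimate_foreground_prob(())

    def test_psi_and_delta_examples(self):
        pilot = make_pilot([1, 1, 0, 0], [1, 0, 0, 0], [0, 0, 0, 0])
        assert estimate_psi(pilot) == 0.25
        pilot2 = make_pilot([1, 1, 0], [0, 1, 0], [1, 1, 1])
        assert estimate_delta(pilot2) == pytest.approx(1 / 3)
        same = make_pilot([1, 0], [1, 0], [0, 1])
        assert estimate_psi(same) == 0.0 and estimate_delta(same) == 0.0

    def test_error_covariance_hand_example(self):
        pilot = make_pilot([1, 0], [0, 0], [1, 0], h=[0, 0])
        assert estimate_error_covariance(pilot) == pytest.approx(0.5)

    def test_error_covariance_zero_when_L_equals_H(self, rng):
        l = rng.integers(0, 2, 50)
        pilot = make_pilot(rng.integers(0, 2, 50), rng.integers(0, 2, 50), l, h=l)
        assert estimate_error_covariance(pilot) == 0.0

    def test_error_covariance_requires_H(self):
        with pytest.raises(ValueError, match="H"):
            estimate_error_covariance(make_pilot([1], [0], [0]))

    def test_error_covariance_vanishes_for_independent_fields(self, rng):
        n, v = 20, 2000
        a = rng.integers(0, 2, (n, v))
        b = rng.integers(0, 2, (n, v))
        l = rng.integers(0, 2, (n, v))
        h = rng.integers(0, 2, (n, v))
        pilot = PilotDataset(labels_A=a, labels_B=b, labels_L=l, labels_H=h)
        # independent +/-1 differences: cov SE ~ sqrt(var_x var_y / n v)
        se = np.sqrt(0.5 * 0.5 / (n * v))
        assert abs(estimate_error_covariance(pilot)) < 3 * se

    def test_estimators_invariant_to_orderings(self, rng):
        n, v = 6, 30
        arrs = {s: rng.integers(0, 2, (n, v)) for s in "abl"}
        pilot = PilotDataset(labels_A=arrs["a"], labels_B=arrs["b"], labels_L=arrs["l"])
        img_perm = rng.permutation(n)
        vox_perm = rng.permutation(v)
        shuffled = PilotDataset(
            labels_A=arrs["a"][img_perm][:, vox_perm],
            labels_B=arrs["b"][img_perm][:, vox_perm],
            labels_L=arrs["l"][img_perm][:, vox_perm],
        )
        assert estimate_psi(pilot) == estimate_psi(shuffled)
        assert estimate_delta(pilot) == estimate_delta(shuffled)
        s1, _ = estimate_variance(pilot)
        s2, _ = estimate_variance(shuffled)
        assert s1 == pytest.approx(s2, abs=1e-15)


class TestVarianceAndBound:
    def test_sample_variance_hand_example(self):
        d_bar = np.array([0.01, 0.02, 0.03])
        assert d_bar.var(ddof=1) == pytest.approx(1e-4)
        # through the pilot route: one voxel per image reproduces d_bar directly
        pilot = make_pilot(
            [np.array([1] * 100), np.array([1] * 100), np.array([1] * 100)],
            [np.array([0] * 1 + [1] * 99), np.array([0] * 2 + [1] * 98),
             np.array([0] * 3 + [1] * 97)],
            [np.array([1] * 100), np.array([1] * 100), np.array([1] * 100)],
        )
        sigma2, _ = estimate_variance(pilot)
        assert sigma2 == pytest.approx(1e-4)

    def test_constant_dbar_gives_zero_bound(self):
        assert variance_upper_bound(np.full(8, 0.02)) == 0.0

    def test_bound_exceeds_point_estimate(self, rng):
        d = rng.normal(0.02, 0.05, 12)
        ub = variance_upper_bound(d, 80.0, 300, 100, rng)
        assert ub > d.var(ddof=1)

    def test_bound_coverage(self, baseline_spatial):
        """Upper gamma% bound covers the true variance in >= gamma% of pilots."""
        from segpower import simulate_images

        config = baseline_config(baseline_spatial, n_images=10)
        truth = variance_dirichlet(0.15, 0.03, omega=128.0, rho_bar=baseline_spatial.rho_bar)
        rng = np.random.default_rng(915)
        reps, gamma = 400, 80.0
        hits = 0
        for _ in range(reps):
            _, d_bar, _ = simulate_images(config, 10, rng)
            hits += variance_upper_bound(d_bar, gamma, 300, 100, rng) >= truth
        se = np.sqrt(gamma / 100 * (1 - gamma / 100) / reps)
        assert hits / reps >= gamma / 100 - 3 * se


class TestDesignFactorAndRho:
    def test_case_study_design_factor(self):
        f = estimate_design_factor(0.134, 0.0402, 0.00231)
        assert f == pytest.approx(0.017449, abs=1e-6)

    def test_limits_and_validation(self):
        assert estimate_design_factor(0.2, 0.1, 0.2 - 0.01) == 1.0
        assert estimate_design_factor(0.2, 0.1, 0.0) == 0.0
        with pytest.warns(SegpowerWarning):
            assert estimate_design_factor(0.2, 0.1, 0.5) == 1.0
        with pytest.raises(ValueError):
            estimate_design_factor(0.01, 0.2, 0.001)

    def test_design_factor_variance_round_trip(self):
        for f in (0.017449, 0.3, 1.0):
            sigma2 = variance_dirichlet(0.134, 0.0402, f)
            assert estimate_design_factor(0.134, 0.0402, sigma2) == pytest.approx(
                f, abs=1e-12
            )

    def test_rho_bar_inverts_dirichlet_variance(self):
        for omega, rho in ((128.0, 0.05), (8.0, 0.5), (1024.0, 0.0)):
            sigma2 = variance_dirichlet(0.15, 0.03, omega=omega, rho_bar=rho)
            assert estimate_rho_bar(sigma2, 0.15, 0.03, omega) == pytest.approx(
                rho, abs=1e-12
            )

    def test_rho_bar_degenerate_cases(self):
        psi, delta, omega = 0.15, 0.03, 64.0
        pure_dirichlet = (psi - delta**2) / (omega + 1)
        assert estimate_rho_bar(pure_dirichlet, psi, delta, omega) == pytest.approx(0.0)
        assert estimate_rho_bar(psi - delta**2, psi, delta, omega) == pytest.approx(1.0)
        with pytest.warns(SegpowerWarning):
            assert estimate_rho_bar(0.0, psi, delta, omega) == 0.0


class TestDirichletPrecision:
    def test_identical_images_cap(self):
        counts = np.tile([10, 80, 10], (5, 1))
        with pytest.warns(SegpowerWarning, match="variability"):
            assert fit_dirichlet_multinomial_precision(counts) == OMEGA_CAP

    def test_two_category_fit_matches_beta_binomial_mle(self, rng):
        """Reduced two-category fit equals an independent beta-binomial MLE."""
        true_omega, n_img, v = 50.0, 80, 120
        p = 0.3
        th = rng.beta(true_omega * p, true_omega * (1 - p), n_img)
        k = rng.binomial(v, th)
        counts = np.column_stack([k, v - k])
        ours = fit_dirichlet_multinomial_precision(counts, tol=1e-10)
        m = k.sum() / (n_img * v)

        def nll(log_w):
            w = np.exp(log_w)
            return -stats.betabinom.logpmf(k, v, w * m, w * (1 - m)).sum()

        res = optimize.minimize_scalar(
            nll, bounds=(np.log(1e-2), np.log(1e6)), method="bounded",
            options={"xatol": 1e-12},
        )
        assert ours == pytest.approx(np.exp(res.x), rel=1e-4)

    def test_absent_category_reduces_dimension(self, rng):
        k = rng.binomial(50, rng.beta(20 * 0.3, 20 * 0.7, 30))
        counts = np.column_stack([k, 50 - k, np.zeros(30, dtype=int)])
        with pytest.warns(SegpowerWarning, match="absent"):
            w = fit_dirichlet_multinomial_precision(counts)
        assert 0 < w < OMEGA_CAP

    def test_recovery_from_sparse_independent_voxels(self, rng):
        """Counts from the generative model recover omega reasonably."""
        omega, n_img, v = 64.0, 100, 256
        p = np.array([0.06, 0.85, 0.09])
        o = rng.dirichlet(omega * p, size=n_img)
        counts = np.array([rng.multinomial(v, ok) for ok in o])
        w = fit_dirichlet_multinomial_precision(counts)
        assert abs(w - omega) / omega < 0.5

    def test_spacing_derivation(self):
        cfg = EstimationConfig(sigma_rho=0.7)
        assert cfg.spacing() == int(np.ceil(0.49 * np.log(100)))  # = 3
        assert EstimationConfig(sparse_spacing=4).spacing() == 4


class TestEstimateAll:
    def test_identical_algorithms_rejected(self):
        a = np.ones((3, 8), dtype=int)
        pilot = PilotDataset(labels_A=a, labels_B=a, labels_L=np.zeros((3, 8), dtype=int))
        with pytest.raises(ValueError, match="disagreement"):
            estimate_all(pilot)

    def test_mdd_correction_requires_H(self, rng):
        pilot = PilotDataset(
            labels_A=rng.integers(0, 2, (4, 16)),
            labels_B=rng.integers(0, 2, (4, 16)),
            labels_L=rng.integers(0, 2, (4, 16)),
        )
        with pytest.raises(ValueError, match="H"):
            estimate_all(pilot, delta_mdd_H=0.05)

    def test_populates_all_fields_with_H(self, rng, baseline_spatial):
        from segpower import ReferenceErrorModel, generate_synthetic_pilot

        config = baseline_config(baseline_spatial, n_images=25, seed=4)
        ref = ReferenceErrorModel(pa=0.246, pb=0.195, pl=0.210, ph=0.214, cov_ab_lh=-0.0029)
        pilot = generate_synthetic_pilot(config, ref, rng=rng)
        est = estimate_all(
            pilot, delta_mdd_H=0.05,
            config=EstimationConfig(boot_outer=200, boot_inner=100, sigma_rho=0.7),
        )
        for name in ("psi_hat", "delta_hat", "sigma2_hat", "sigma2_upper", "f_hat",
                     "omega_hat", "rho_bar_hat", "pa_hat", "pb_hat", "pl_hat",
                     "ph_hat", "cov_hat", "delta_mdd_hat"):
            assert getattr(est, name) is not None
        assert est.sigma2_upper >= est.sigma2_hat
        assert 0 <= est.f_hat <= 1
        # the corrected MDD is the adjustment formula applied to the estimates
        expected = est.delta_mdd_hat
        manual = (0.05 + 2 * (est.pa_hat - est.pb_hat) * (est.pl_hat - est.ph_hat)
                  + 2 * est.cov_hat)
        assert expected == pytest.approx(manual, abs=1e-15)
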