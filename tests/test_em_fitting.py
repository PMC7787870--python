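"""Generalized EM: roughening updates of g, gamma updates, recovery runs."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import logit

from hmrfmix import (
    EffectSizeDistribution,
    FitConfig,
    IsingParams,
    SummaryData,
    VoxelLattice,
    fit,
    gibbs_prior,
    update_g,
    update_gamma,
)


class TestUpdateG:
    def test_one_step_matches_hand_fixed_point(self):
        """One weighted NPMLE step on 3 voxels x 2 mass points, by hand."""
        y = np.array([0.1, 0.35, 0.5])
        w = np.array([0.2, 0.9, 0.6])
        data = SummaryData(y=y, n1=50, n2=50, family="normal")
        g0 = EffectSizeDistribution(np.array([0.2, 0.4]), np.array([0.5, 0.5]))
        # independent arithmetic: r_sb ∝ p_b N(y_s; t_b, c_n^2)
        F = stats.norm.pdf(y[:, None], loc=np.array([0.2, 0.4])[None, :], scale=0.2)
        num = F * 0.5
        r = num / num.sum(axis=1, keepdims=True)
        expected = (w @ r) / w.sum()
        out = update_g(data, w, g0, n_inner=1)
        np.testing.assert_allclose(out.probs, expected, atol=1e-12)

    def test_single_mass_point_stays_degenerate(self):
        data = SummaryData(y=np.array([0.1, 0.4]), n1=50, n2=50)
        g0 = EffectSizeDistribution(np.array([0.3]), np.array([1.0]))
        out = update_g(data, np.array([1.0, 1.0]), g0, n_inner=5)
        np.testing.assert_allclose(out.probs, [1.0])

    def test_mass_concentrates_under_likelihood_domination(self):
        # y exactly at one mass point with a tiny sampling scale
        data = SummaryData(
            y=np.full(30, 0.4), n1=50, n2=50, family="normal", c_n=0.01
        )
        g0 = EffectSizeDistribution(
            np.array([0.2, 0.4, 0.6]), np.full(3, 1 / 3)
        )
        out = update_g(data, np.ones(30), g0, n_inner=30)
        assert out.probs[1] > 0.999

    def test_zero_weights_leave_g_unchanged(self):
        data = SummaryData(y=np.array([0.1, 0.4]), n1=50, n2=50)
        g0 = EffectSizeDistribution(np.array([0.2, 0.4]), np.array([0.3, 0.7]))
        out = update_g(data, np.zeros(2), g0, n_inner=10)
        np.testing.assert_array_equal(out.probs, g0.probs)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_output_is_a_distribution(self, seed):
        rng = np.random.default_rng(seed)
        data = SummaryData(y=rng.normal(0, 0.4, 40), n1=30, n2=30, family="t")
        g0 = EffectSizeDistribution(
            np.linspace(-1, 1, 21) + 1e-3, np.full(21, 1 / 21)
        )
        out = update_g(data, rng.random(40), g0, n_inner=7)
        assert np.all(out.probs >= 0)
        assert out.probs.sum() == pytest.approx(1.0, abs=1e-10)


class TestUpdateGamma:
    def test_fixed_point_when_posterior_equals_prior(self):
        lat = VoxelLattice.full((10, 10, 10))
        cur = IsingParams(0.1, -1.0)
        draws = gibbs_prior(cur, lat, 600, seed=1, burn_in=200)
        cfg = FitConfig(gamma_sweeps=600, gamma_burn_in=200)
        new = update_gamma(cur, draws, lat, cfg, seed=2)
        assert abs(new.gamma1 - cur.gamma1) < 0.15
        assert abs(new.gamma2 - cur.gamma2) < 0.15

    def test_degenerate_candidate_rejected(self):
        lat = VoxelLattice.full((6, 6, 6))
        cur = IsingParams(0.1, -1.0)
        draws = gibbs_prior(cur, lat, 300, seed=3, burn_in=100)
        cfg = FitConfig()
        frozen = IsingParams(8.0, 8.0)  # deep in the phase-transition regime
        new = update_gamma(cur, draws, lat, cfg, seed=4, candidate=frozen)
        assert new == cur

    def test_gamma2_recovers_calibrated_value(self):
        """With gamma1 at truth and g known, the external-field update
        converges to the value the calibration oracle produces."""
        from hmrfmix import (
            ModelParams,
            SimConfig,
            calibrate_gamma2,
            gibbs_posterior,
            simulate_dataset,
        )

        lat = VoxelLattice.full((10, 10, 10))
        g2_true = calibrate_gamma2(0.15, 0.2, lat, seed=5)
        cfg = SimConfig(n=200, dims=(10, 10, 10), gamma1=0.15, target_prop=0.2)
        truth, data, lattice = simulate_dataset(cfg, seed=6, gamma2=g2_true)
        # true effect-size distribution, discretized
        pts = np.linspace(0.05, 0.55, 26)
        w = stats.norm.pdf(pts, 0.3, 0.1)
        g_true = EffectSizeDistribution(pts, w / w.sum())
        cur = IsingParams(0.15, -2.5)
        hist = []
        for it in range(14):
            fc = FitConfig(
                fix_gamma1=True, gamma_step=1.0 / (1 + 0.2 * it),
                gamma_sweeps=400, gamma_burn_in=100,
            )
            draws = gibbs_posterior(
                ModelParams(cur, g_true), data, lattice, 400,
                seed=100 + it, burn_in=100,
            )
            cur = update_gamma(cur, draws, lattice, fc, seed=200 + it)
            hist.append(cur.gamma2)
        assert np.mean(hist[-5:]) == pytest.approx(g2_true, abs=0.2)


class TestFit:
    def test_recovery_under_independence(self):
        """gamma1 = 0: fitted g centers near 0.3, posterior separates truth."""
        from hmrfmix import SimConfig, simulate_dataset

        cfg = SimConfig(n=200, dims=(10, 10, 10), gamma1=0.0, target_prop=0.2)
        g2 = float(logit(0.2))
        truth, data, lattice = simulate_dataset(cfg, seed=10, gamma2=g2)
        fc = FitConfig(
            B=100, max_iter=12, fix_gamma=True, gamma_init=IsingParams(0.0, g2)
        )
        res = fit(data, lattice, fc, seed=11)
        pos = res.params.g.probs @ res.params.g.mass_points
        assert pos == pytest.approx(0.3, abs=0.05)
        # AUC of posterior nonnull probability against the true labels
        omega = res.posterior_nonnull
        auc = stats.mannwhitneyu(
            omega[truth.theta == 1], omega[truth.theta == 0]
        ).statistic / ((truth.theta == 1).sum() * (truth.theta == 0).sum())
        assert auc > 0.8

    def test_null_only_data_yields_small_posteriors(self):
        rng = np.random.default_rng(12)
        lat = VoxelLattice.full((8, 8, 8))
        y = 0.2 * rng.standard_t(98, lat.m)
        data = SummaryData(y=y, n1=50, n2=50, family="t")
        fc = FitConfig(B=60, max_iter=10)
        res = fit(data, lat, fc, seed=13)
        assert res.posterior_nonnull.mean() < 0.2

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(14)
        lat = VoxelLattice.full((5, 5, 5))
        data = SummaryData(y=rng.normal(0, 0.3, lat.m), n1=40, n2=40)
        fc = FitConfig(B=30, max_iter=3, fix_gamma=True,
                       gamma_init=IsingParams(0.1, -1.0))
        a = fit(data, lat, fc, seed=15)
        b = fit(data, lat, fc, seed=15)
        np.testing.assert_array_equal(a.posterior_nonnull, b.posterior_nonnull)
        np.testing.assert_array_equal(a.params.g.probs, b.params.g.probs)

    def test_rejects_nonfinite_input(self):
        lat = VoxelLattice.full((2, 2, 2))
        with pytest.raises(ValueError):
            SummaryData(y=np.array([np.inf] * 8), n1=5, n2=5)

    def test_trajectory_records_each_iteration(self):
        rng = np.random.default_rng(16)
        lat = VoxelLattice.full((4, 4, 4))
        data = SummaryData(y=rng.normal(0, 0.3, lat.m), n1=40, n2=40)
        fc = FitConfig(B=20, max_iter=4, fix_gamma=True,
                       gamma_init=IsingParams(0.0, -1.0))
        res = fit(data, lat, fc, seed=17)
        assert len(res.trajectory) == res.n_iterations
        assert {"iteration", "gamma1", "gamma2", "g_mean"} <= set(
            res.trajectory[0]
        )
        assert np.all((res.posterior_nonnull >= 0) & (res.posterior_nonnull <= 1))
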