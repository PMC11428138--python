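import numpy as np
import pytest

from specmap import analysis, synthetic
from specmap.analysis import (
    diffusion_corrected_F,
    diffusion_profile,
    free_energy_landscape,
    free_energy_profile,
    markovianity_profile,
    mfpt,
    min_free_energy_path,
)
from specmap.exceptions import DisconnectedEndpointsError, SpecmapWarning


class TestFreeEnergyProfile:
    def test_uniform_samples_flat(self, rng):
        z = rng.uniform(0, 1, 200_000)
        prof = free_energy_profile(z, bins=20)
        assert np.nanmax(prof.F) < 0.1

    def test_gaussian_recovers_quadratic(self, rng):
        z = rng.standard_normal(500_000)
        prof = free_energy_profile(z, bins=50, range=(-3, 3))
        expected = prof.centers**2 / 2.0
        expected -= expected.min()
        good = prof.counts >= 100
        np.testing.assert_allclose(prof.F[good], expected[good], atol=0.1)

    def test_double_well_barrier(self, dw_traj):
        # Langevin oracle: beta U = 5 (z^2-1)^2, barrier 5 k_BT
        prof = free_energy_profile(dw_traj, bins=50)
        barrier_bin = np.argmin(np.abs(prof.centers))
        assert prof.F[barrier_bin] == pytest.approx(5.0, abs=0.5)

    def test_min_is_zero_and_mask(self, rng):
        z = rng.standard_normal(1000)
        prof = free_energy_profile(z, bins=50, range=(-10, 10))
        assert np.nanmin(prof.F) == 0.0
        assert np.isnan(prof.F[0])  # far tail unpopulated

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            free_energy_profile(np.array([]))

    def test_affine_rescaling_invariance(self, rng):
        z = rng.standard_normal(100_000)
        p1 = free_energy_profile(z, bins=40, range=(-4, 4))
        p2 = free_energy_profile(3.0 * z + 7.0, bins=40, range=(-5, 19))
        np.testing.assert_allclose(p1.F, p2.F, atol=1e-10)


class TestMinFreeEnergyPath:
    def test_flat_landscape_shortest_path(self):
        land = analysis.FreeEnergyLandscape(
            x_centers=np.arange(10.0), y_centers=np.arange(10.0),
            F=np.ones((10, 10)), counts=np.ones((10, 10)), beta=1.0,
        )
        out = min_free_energy_path(land, (0, 0), (9, 9))
        # 8-connected flat grid: the diagonal (10 bins) is cost-optimal
        assert len(out["path"]) == 10
        assert out["cost"] == pytest.approx(9.0)

    def test_crosses_ridge_at_saddle(self):
        # constructed grid: vertical ridge with a notch at row 3
        F = np.zeros((7, 7))
        F[:, 3] = 10.0
        F[3, 3] = 1.0
        land = analysis.FreeEnergyLandscape(
            x_centers=np.arange(7.0), y_centers=np.arange(7.0),
            F=F, counts=np.ones_like(F), beta=1.0,
        )
        out = min_free_energy_path(land, (3, 0), (3, 6))
        path = {tuple(p) for p in out["path"]}
        assert (3, 3) in path
        assert out["barrier"] == pytest.approx(1.0)

    def test_barrier_at_least_endpoints(self, dw_traj):
        Z = np.column_stack([dw_traj[:-1], dw_traj[1:]])
        land = free_energy_landscape(Z[::5], bins=30)
        i0 = np.unravel_index(np.nanargmin(np.where(land.x_centers[:, None] < 0, land.F, np.nan)), land.F.shape)
        i1 = np.unravel_index(np.nanargmin(np.where(land.x_centers[:, None] > 0, land.F, np.nan)), land.F.shape)
        out = min_free_energy_path(land, i0, i1)
        assert out["barrier"] >= land.F[i0] - 1e-12
        assert out["barrier"] >= land.F[i1] - 1e-12

    def test_disconnected_raises(self):
        F = np.full((5, 5), np.nan)
        F[0, 0] = 0.0
        F[4, 4] = 0.0
        land = analysis.FreeEnergyLandscape(
            x_centers=np.arange(5.0), y_centers=np.arange(5.0),
            F=F, counts=np.ones_like(F), beta=1.0,
        )
        with pytest.raises(DisconnectedEndpointsError):
            min_free_energy_path(land, (0, 0), (4, 4))


class TestMarkovianity:
    def test_never_visiting_ts_gives_zero(self, rng):
        z = rng.normal(5.0, 0.1, 5000)
        with pytest.warns(SpecmapWarning):
            prof = markovianity_profile(z, ts=(-1.0, 1.0))
        assert prof.p_star == 0.0

    def test_entirely_inside_ts_degenerate(self, rng):
        z = rng.uniform(-0.5, 0.5, 5000)
        with pytest.warns(SpecmapWarning):
            prof = markovianity_profile(z, ts=(-1.0, 1.0))
        assert prof.degenerate
        assert prof.p_star == 1.0

    def test_markovian_double_well_quarter(self, dw_traj):
        prof = markovianity_profile(dw_traj, ts=(-0.2, 0.2), bins=50)
        assert prof.p_star == pytest.approx(0.25, abs=0.04)

    def test_profile_in_unit_interval(self, dw_traj):
        prof = markovianity_profile(dw_traj[:200_000], ts=(-0.3, 0.3))
        valid = np.isfinite(prof.p_ts_given_z)
        assert np.all(prof.p_ts_given_z[valid] >= 0)
        assert np.all(prof.p_ts_given_z[valid] <= 1)

    def test_invalid_interval(self, rng):
        with pytest.raises(ValueError):
            markovianity_profile(rng.standard_normal(100), ts=(1.0, -1.0))


class TestDiffusionProfile:
    def test_free_brownian_recovery(self):
        rng = np.random.default_rng(0)
        dt = 1e-3
        z = np.cumsum(np.sqrt(2 * dt) * rng.standard_normal(400_000))
        prof = diffusion_profile(z, dt=dt, bins=10, lags=(1, 2, 3, 4, 5))
        valid = np.isfinite(prof.D)
        assert valid.sum() >= 5
        np.testing.assert_allclose(prof.D[valid], 1.0, rtol=0.1)

    def test_static_trajectory_zero(self):
        z = np.full(10_000, 0.7)
        prof = diffusion_profile(z, dt=1e-3, bins=5)
        valid = np.isfinite(prof.D)
        assert valid.any()
        np.testing.assert_allclose(prof.D[valid], 0.0, atol=1e-15)

    def test_ou_slope_independent_of_spring(self):
        # closed form: OU MSD short-lag slope equals the noise D
        dt = 1e-3
        for kappa in (0.5, 5.0):
            cfg = synthetic.LangevinConfig(
                potential=synthetic.harmonic(kappa), dt=dt,
                n_steps=2_000_000, seed=3,
            )
            z = synthetic.simulate_langevin(cfg)
            prof = diffusion_profile(z, dt=dt, bins=5, lags=(1, 2, 3))
            center = np.nanmedian(prof.D)
            assert center == pytest.approx(1.0, rel=0.1)

    def test_requires_two_lags(self, rng):
        with pytest.raises(ValueError):
            diffusion_profile(rng.standard_normal(100), dt=1.0, lags=(1,))


class TestDiffusionCorrectedF:
    def _profiles(self, rng, D_values):
        z = rng.standard_normal(50_000)
        F = free_energy_profile(z, bins=20, range=(-3, 3))
        D = analysis.DiffusionProfile(
            centers=F.centers.copy(), D=np.asarray(D_values, dtype=float),
            counts=np.ones(20), lags=np.array([1.0, 2.0]),
        )
        return F, D

    def test_constant_D_identity(self, rng):
        F, D = self._profiles(rng, np.full(20, 2.5))
        FD, disc = diffusion_corrected_F(F, D)
        valid = np.isfinite(F.F)
        np.testing.assert_allclose(FD.F[valid], F.F[valid], atol=1e-12)
        assert disc == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_e_fold_shift(self, rng):
        D_vals = np.full(20, 1.0)
        bump = 15
        D_vals[bump] = np.e
        F, D = self._profiles(rng, D_vals)
        ref = int(np.nanargmin(np.where(np.isfinite(F.F), F.F, np.inf)))
        assert ref != bump
        FD, _ = diffusion_corrected_F(F, D)
        assert F.F[bump] - FD.F[bump] == pytest.approx(1.0, abs=1e-10)

    def test_mild_variation_below_kbt(self, rng):
        rng2 = np.random.default_rng(1)
        D_vals = np.exp(rng2.uniform(-0.5, 0.5, 20))  # factor < e
        F, D = self._profiles(rng, D_vals)
        _, disc = diffusion_corrected_F(F, D)
        assert disc < 1.0

    def test_bin_mismatch(self, rng):
        F, D = self._profiles(rng, np.ones(20))
        D.centers = D.centers + 0.1
        with pytest.raises(ValueError):
            diffusion_corrected_F(F, D)


class TestMFPT:
    def test_telegraph_rates_within_ci(self):
        k1, k2 = 0.01, 0.004
        labels = synthetic.telegraph(k1, k2, 1_000_000, dt=1.0, seed=0)
        out = mfpt(labels, dt=1.0, lags=(1, 2, 5, 10), n_boot=100)
        est01 = out[(0, 1)]
        est10 = out[(1, 0)]
        assert est01.ci[0] <= 1.0 / k1 <= est01.ci[1]
        assert est10.ci[0] <= 1.0 / k2 <= est10.ci[1]
        assert est01.ci[0] <= est01.plateau <= est01.ci[1]

    def test_symmetric_rates_ratio_one(self):
        labels = synthetic.telegraph(0.01, 0.01, 1_000_000, dt=1.0, seed=1)
        out = mfpt(labels, dt=1.0, lags=(1, 2, 5), n_boot=20)
        ratio = out[(0, 1)].plateau / out[(1, 0)].plateau
        assert ratio == pytest.approx(1.0, rel=0.1)

    def test_ratio_matches_inverse_populations(self):
        # detailed balance oracle: pi_0 k_01 = pi_1 k_10 so
        # MFPT_01 / MFPT_10 = k2/k1 = pi_0/pi_1
        k1, k2 = 0.02, 0.005
        labels = synthetic.telegraph(k1, k2, 2_000_000, dt=1.0, seed=2)
        out = mfpt(labels, dt=1.0, lags=(1, 2, 5), n_boot=20)
        pop0 = np.mean(labels == 0)
        expected = pop0 / (1.0 - pop0)
        assert out[(0, 1)].plateau / out[(1, 0)].plateau == pytest.approx(
            expected, rel=0.15
        )

    def test_no_transitions_infinite(self):
        labels = np.concatenate([np.zeros(100, dtype=int), np.ones(1, dtype=int)])
        out = mfpt(labels, dt=1.0, lags=(1, 2), n_boot=5)
        assert np.isinf(out[(1, 0)].plateau)

    def test_single_state_raises(self):
        with pytest.raises(ValueError):
            mfpt(np.zeros(100, dtype=int))
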