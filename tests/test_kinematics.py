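import numpy as np
import pandas as pd
import pytest

from shoalkit import kinematics as kin
from shoalkit.trajectory import TrajectorySet, VelocityField, derive_velocities
from tests.conftest import make_trajectory, trajectory_from_array


def velocity_field(vectors, fps=15.0, frame=0):
    n = len(vectors)
    df = pd.DataFrame(
        {"frame": frame, "id": np.arange(n),
         "vx": [v[0] for v in vectors], "vy": [v[1] for v in vectors],
         "vz": [v[2] for v in vectors]}
    )
    return VelocityField(df, fps=fps)


class TestFrameQuantities:
    def test_mean_speed(self):
        v = velocity_field([(10, 0, 0), (0, 20, 0)])
        assert kin.frame_speed(v, 0) == pytest.approx(15.0)

    def test_stationary_speed_zero(self):
        v = velocity_field([(0, 0, 0), (0, 0, 0)])
        assert kin.frame_speed(v, 0) == 0.0

    def test_speed_matches_direct_mean_of_norms(self, rng):
        vecs = rng.normal(size=(50, 3)) * 20
        v = velocity_field(vecs)
        assert kin.frame_speed(v, 0) == pytest.approx(
            np.linalg.norm(vecs, axis=1).mean()
        )

    def test_polarisation_parallel_is_one(self):
        v = velocity_field([(3, 0, 0), (7, 0, 0), (1, 0, 0)])
        assert kin.frame_polarisation(v, 0) == pytest.approx(1.0)

    def test_polarisation_antiparallel_is_zero(self):
        v = velocity_field([(5, 0, 0), (-5, 0, 0)])
        assert kin.frame_polarisation(v, 0) == pytest.approx(0.0, abs=1e-12)

    def test_polarisation_isotropic_matches_monte_carlo_baseline(self, rng):
        # independent sampler: mean resultant length of N uniform unit vectors
        n = 10_000
        draws = rng.normal(size=(40, n, 3))
        draws /= np.linalg.norm(draws, axis=2, keepdims=True)
        baseline = np.linalg.norm(draws.mean(axis=1), axis=1)
        vecs = rng.normal(size=(n, 3))
        phi = kin.polarisation(vecs)
        assert phi < 5 * baseline.mean()  # small, O(N^-1/2)
        assert abs(phi - baseline.mean()) < 4 * baseline.std() + 5e-3

    def test_polarisation_excludes_zero_speed_rows(self):
        v = velocity_field([(1, 0, 0), (0, 0, 0), (1, 0, 0)])
        assert kin.frame_polarisation(v, 0) == pytest.approx(1.0)

    def test_all_zero_frame_is_undefined(self):
        v = velocity_field([(0, 0, 0)])
        with pytest.raises(kin.UndefinedValueError):
            kin.frame_polarisation(v, 0)

    def test_nn_distance_pair(self):
        t = make_trajectory({0: {0: (0, 0, 0), 1: (10, 0, 0)}})
        assert kin.frame_nearest_neighbour_distance(t, 0) == pytest.approx(10.0)

    def test_nn_distance_collinear_triple(self):
        t = make_trajectory({0: {0: (0, 0, 0), 1: (1, 0, 0), 2: (3, 0, 0)}})
        assert kin.frame_nearest_neighbour_distance(t, 0) == pytest.approx(4.0 / 3.0)

    def test_nn_distance_matches_brute_force(self, rng):
        pts = rng.uniform(0, 100, size=(50, 3))
        d = np.linalg.norm(pts[:, None] - pts[None], axis=2)
        np.fill_diagonal(d, np.inf)
        expected = d.min(axis=1).mean()
        t = trajectory_from_array(pts[None])
        assert kin.frame_nearest_neighbour_distance(t, 0) == pytest.approx(expected)

    def test_single_fish_nn_undefined(self):
        t = make_trajectory({0: {0: (0, 0, 0)}})
        with pytest.raises(kin.UndefinedValueError):
            kin.frame_nearest_neighbour_distance(t, 0)


class TestInvariances:
    """Phi is rotation/relabelling invariant; l_nn is Euclidean-invariant
    and scales linearly under dilation; kappa is dimensionless."""

    def test_polarisation_rotation_and_relabelling_invariant(self, rng):
        vecs = rng.normal(size=(30, 3))
        # random rotation via QR
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        phi0 = kin.polarisation(vecs)
        assert 0.0 <= phi0 <= 1.0
        assert kin.polarisation(vecs @ q.T) == pytest.approx(phi0)
        assert kin.polarisation(vecs[rng.permutation(30)]) == pytest.approx(phi0)

    def test_nn_distance_euclidean_invariance_and_dilation(self, rng):
        pts = rng.uniform(0, 50, size=(20, 3))
        base = kin.nearest_neighbour_distances(pts).mean()
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        moved = pts @ q.T + np.array([5.0, -3.0, 11.0])
        assert kin.nearest_neighbour_distances(moved).mean() == pytest.approx(base)
        assert kin.nearest_neighbour_distances(2.5 * pts).mean() == pytest.approx(2.5 * base)

    def test_kappa_invariant_under_spatial_rescaling(self, rng):
        from tests.conftest import correlated_steps

        pos = np.cumsum(correlated_steps(rng, 600, 8, scale=3.0), axis=0) + 500
        for scale in (1.0, 7.0):
            t = trajectory_from_array(scale * pos)
            st = kin.window_state(t, derive_velocities(t), (0, 600), acf_max_lag=5.0)
            if scale == 1.0:
                kappa0 = st.kappa
            else:
                assert st.kappa == pytest.approx(kappa0, rel=1e-6)


class TestScalarAcf:
    def test_white_noise_uncorrelated(self, rng):
        series = rng.normal(size=5000)
        acf = kin.scalar_acf(series, fps=1.0, max_lag=20)
        assert acf.values[0] == pytest.approx(1.0)
        assert np.all(np.abs(acf.values[1:]) < 0.08)

    def test_ar1_matches_closed_form(self, rng):
        a = 0.8
        x = np.empty(60_000)
        x[0] = 0.0
        eps = rng.normal(size=len(x))
        for i in range(1, len(x)):
            x[i] = a * x[i - 1] + eps[i]
        acf = kin.scalar_acf(x, fps=1.0, max_lag=12)
        assert np.allclose(acf.values, a ** np.arange(13), atol=0.03)

    def test_periodic_series_peaks_at_period(self):
        x = np.sin(2 * np.pi * np.arange(3000) / 50.0)
        acf = kin.scalar_acf(x, fps=1.0, max_lag=120)
        assert acf.values[50] > 0.9
        assert acf.values[100] > 0.8
        assert acf.values[25] < -0.8

    def test_constant_series_undefined(self):
        with pytest.raises(kin.UndefinedValueError):
            kin.scalar_acf(np.ones(100), fps=1.0, max_lag=5)


class TestOrientationAcf:
    def test_straight_swimmers_stay_at_one(self, rng):
        u = rng.normal(size=(1, 5, 3))
        pos = 100 + np.cumsum(np.repeat(u, 200, axis=0), axis=0)
        t = trajectory_from_array(pos)
        acf = kin.orientation_acf(derive_velocities(t), max_lag=5.0)
        assert np.allclose(acf.values, 1.0, atol=1e-9)

    def test_rerandomised_each_frame_decorrelates(self, rng):
        steps = rng.normal(size=(800, 10, 3))
        pos = 1000 + np.cumsum(steps, axis=0)
        t = trajectory_from_array(pos)
        acf = kin.orientation_acf(derive_velocities(t), max_lag=1.0)
        assert acf.values[0] == pytest.approx(1.0)
        assert np.all(np.abs(acf.values[1:]) < 0.05)

    def test_rotational_diffusion_rate_recovered(self, rng):
        """Small-step diffusion on the sphere: ACF = exp(-2 D_r t)."""
        d_r, fps, n, T = 0.5, 50.0, 25, 4000
        dt = 1.0 / fps
        u = rng.normal(size=(n, 3))
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        us = np.empty((T, n, 3))
        for k in range(T):
            kick = np.sqrt(2 * d_r * dt) * rng.normal(size=(n, 3))
            kick -= np.einsum("ij,ij->i", kick, u)[:, None] * u  # tangent plane
            u = u + kick
            u /= np.linalg.norm(u, axis=1, keepdims=True)
            us[k] = u
        pos = 1000 + np.cumsum(us * 30 * dt, axis=0)
        traj = trajectory_from_array(pos, fps=fps)
        acf = kin.orientation_acf(derive_velocities(traj), max_lag=3.0)
        tau = kin.fit_relaxation_time(acf, plateau=None)
        assert tau == pytest.approx(1.0 / (2 * d_r), rel=0.10)


class TestRelaxationFit:
    def make_acf(self, tau, fps=15.0, max_lag=5.0, noise=0.0, rng=None):
        lags = np.arange(int(max_lag * fps) + 1) / fps
        vals = np.exp(-lags / tau)
        if noise:
            vals = vals + rng.normal(scale=noise, size=len(vals))
            vals[0] = 1.0
        return kin.AcfCurve(lags=lags, values=vals, n_pairs=np.ones_like(lags))

    @pytest.mark.parametrize("tau", [1.0, 0.7])
    def test_exact_exponential_recovered(self, tau):
        acf = self.make_acf(tau)
        assert kin.fit_relaxation_time(acf) == pytest.approx(tau, rel=1e-9)

    def test_noisy_exponential_within_5_percent(self, rng):
        acf = self.make_acf(1.3, noise=0.02, rng=rng)
        assert kin.fit_relaxation_time(acf) == pytest.approx(1.3, rel=0.05)

    def test_plateau_is_subtracted(self):
        lags = np.arange(301) / 15.0
        vals = 0.6 * np.exp(-lags / 0.8) + 0.4
        acf = kin.AcfCurve(lags=lags, values=vals, n_pairs=np.ones_like(lags))
        assert kin.fit_relaxation_time(acf) == pytest.approx(0.8, rel=1e-6)

    def test_non_decaying_acf_errors(self):
        lags = np.arange(20) / 15.0
        acf = kin.AcfCurve(lags=lags, values=np.ones(20), n_pairs=np.ones(20))
        with pytest.raises(ValueError):
            kin.fit_relaxation_time(acf, plateau=None)


class TestWindowState:
    def test_parallel_constant_swimmers(self, rng):
        u = np.array([0.6, 0.8, 0.0])
        offsets = rng.uniform(0, 50, size=(6, 3))
        # constant heading, tiny jitter so the ACF is not identically 1
        steps = u * 2.0 + rng.normal(scale=1e-3, size=(900, 6, 3))
        pos = 500 + offsets + np.cumsum(steps, axis=0)
        t = trajectory_from_array(pos)
        st = kin.window_state(t, derive_velocities(t), (0, 900), acf_max_lag=10.0)
        assert st.phi_mean > 0.999
        assert st.v0_mean == pytest.approx(2.0 * 15.0, rel=1e-3)
        assert st.lp == pytest.approx(st.v0_mean * st.tau)

    def test_kappa_is_definitional_ratio(self, random_walk_traj):
        st = kin.window_state(
            random_walk_traj, derive_velocities(random_walk_traj), (0, 40), acf_max_lag=1.0
        )
        assert st.kappa == pytest.approx(st.lp / st.lnn_mean)

    def test_record_round_trip_fields(self, random_walk_traj):
        st = kin.window_state(
            random_walk_traj, derive_velocities(random_walk_traj), (0, 40),
            acf_max_lag=1.0, group_label="Y1",
        )
        rec = st.to_record()
        assert rec["group"] == "Y1"
        assert rec["kappa"] == pytest.approx(st.kappa)
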