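"""Delay estimation, embedding, FNN, correlation dimension, Lyapunov
exponent and surrogate testing, validated against analytic and
brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mcdm.phase_space import (
    DelayNotFoundError, EmbeddedTrajectory, EmbeddingParams,
    correlation_dimension, embed, estimate_delay, estimate_embedding_dim,
    lyapunov_wolf, phase_randomized_surrogate, surrogate_test,
)
from mcdm.synthetic import TimeSeries, simulate_system


def _brute_force_delay(x, max_lag):
    """Independent lag scan of the non-centered autocorrelation."""
    n = len(x)
    r0 = np.sum(x * x) / n
    threshold = (1 - np.exp(-1)) * r0
    for lag in range(1, max_lag + 1):
        if np.sum(x[: n - lag] * x[lag:]) / n < threshold:
            return lag
    return None


class TestEstimateDelay:
    def test_period_100_sine_gives_15(self, period100_sine):
        # first integer lag with cos(2 pi tau / 100) < 1 - 1/e
        assert estimate_delay(period100_sine, 100) == 15

    def test_white_noise_gives_1(self):
        noise = simulate_system("white_noise", {}, 2000, seed=8)
        assert estimate_delay(noise, 50) == 1

    @pytest.mark.parametrize("name, params, n", [
        ("sine", {"frequency": 9.7, "sampling_rate": 1000.0}, 3000),
        ("logistic", {}, 2000),
        ("white_noise", {}, 2000),
        ("lorenz", {}, 5000),
    ])
    def test_exact_agreement_with_brute_force_scan(self, name, params, n):
        series = simulate_system(name, params, n, seed=3)
        oracle = _brute_force_delay(series.values, 200)
        assert estimate_delay(series, 200) == oracle

    def test_constant_series_raises_with_last_value(self):
        series = TimeSeries(np.full(500, 2.0), 1.0)
        with pytest.raises(DelayNotFoundError, match="delay not found") as err:
            estimate_delay(series, 50)
        assert err.value.last_value == pytest.approx(4.0, rel=0.2)


class TestEmbed:
    def test_row_count_formula(self):
        series = TimeSeries(np.arange(1000, dtype=float), 1.0)
        traj = embed(series, EmbeddingParams(tau=10, m=3))
        assert traj.points.shape == (980, 3)

    @given(n=st.integers(20, 400), m=st.integers(1, 5), tau=st.integers(1, 10))
    def test_count_conservation_property(self, n, m, tau):
        if n - (m - 1) * tau < 1:
            return
        series = TimeSeries(np.sin(np.arange(n, dtype=float)), 1.0)
        traj = embed(series, EmbeddingParams(tau=tau, m=m))
        assert len(traj) == n - (m - 1) * tau
        # row i is (x_i, x_{i+tau}, ..., x_{i+(m-1)tau})
        np.testing.assert_array_equal(
            traj.points[0], series.values[: (m - 1) * tau + 1: tau]
        )

    def test_m1_is_identity(self):
        series = TimeSeries(np.arange(50, dtype=float), 1.0)
        traj = embed(series, EmbeddingParams(tau=3, m=1))
        np.testing.assert_array_equal(traj.points[:, 0], series.values)

    def test_too_short_series_rejected(self):
        series = TimeSeries(np.arange(10, dtype=float), 1.0)
        with pytest.raises(ValueError, match="too short"):
            embed(series, EmbeddingParams(tau=4, m=4))


class TestFNN:
    def test_sine_embeds_in_two_dimensions(self, sine_series):
        tau = estimate_delay(sine_series, 200)
        result = estimate_embedding_dim(sine_series, tau=tau, m_max=8)
        assert result.m == 2 and result.converged
        assert result.fractions[1] < result.fractions[0]

    def test_lorenz_fractions_collapse_by_three_dimensions(self, lorenz_series):
        result = estimate_embedding_dim(lorenz_series, tau=10, m_max=6)
        assert result.converged
        assert result.fractions[2] < 0.05  # attractor dimension ~2.05 < 3
        assert result.m <= 4

    def test_iid_noise_does_not_converge(self):
        noise = simulate_system("white_noise", {}, 1000, seed=5)
        with pytest.warns(RuntimeWarning, match="did not satisfy"):
            result = estimate_embedding_dim(noise, tau=1, m_max=8)
        assert not result.converged
        assert result.m == 8

    def test_degenerate_series_rejected(self):
        series = TimeSeries(np.full(200, 1.0), 1.0)
        with pytest.raises(ValueError, match="degenerate"):
            estimate_embedding_dim(series, tau=1)


class TestCorrelationDimension:
    def test_matches_brute_force_oracle_exactly(self, logistic_series):
        traj = embed(TimeSeries(logistic_series.values[:500], 1.0),
                     EmbeddingParams(tau=1, m=3))
        curve = correlation_dimension(traj, n_radii=25)
        pts = traj.points
        d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        off_diag = d[~np.eye(len(pts), dtype=bool)]
        oracle = np.array([(off_diag <= r).sum() for r in curve.radii])
        np.testing.assert_array_equal(curve.c_values, oracle / len(pts) ** 2)

    def test_line_segment_has_dimension_one(self):
        t = np.linspace(0, 1, 5000)
        traj = EmbeddedTrajectory.from_points(np.column_stack([t, 0.5 * t]))
        assert correlation_dimension(traj).slope == pytest.approx(1.0, abs=0.15)

    def test_curve_monotone_and_saturates(self, rng):
        traj = EmbeddedTrajectory.from_points(rng.uniform(0, 1, (500, 2)))
        curve = correlation_dimension(traj)
        assert np.all(np.diff(curve.c_values) >= 0)
        assert curve.c_values[-1] >= 1 - 2 / len(traj)  # j != k normalization
        assert np.all((curve.c_values >= 0) & (curve.c_values <= 1))

    def test_theiler_window_drops_temporal_pairs(self, logistic_series):
        traj = embed(TimeSeries(logistic_series.values[:400], 1.0),
                     EmbeddingParams(tau=1, m=2))
        c0 = correlation_dimension(traj, theiler=0)
        c5 = correlation_dimension(traj, theiler=5)
        assert np.all(c5.c_values <= c0.c_values)
        assert c5.c_values[-1] < c0.c_values[-1]

    def test_too_few_points_rejected(self):
        traj = EmbeddedTrajectory.from_points(np.zeros((1, 2)))
        with pytest.raises(ValueError, match="two points"):
            correlation_dimension(traj)

    def test_coincident_points_rejected(self):
        traj = EmbeddedTrajectory.from_points(np.zeros((50, 2)))
        with pytest.raises(ValueError, match="zero"):
            correlation_dimension(traj)


class TestLyapunovWolf:
    def test_logistic_matches_analytic_ln2(self, logistic_series):
        traj = embed(logistic_series, EmbeddingParams(tau=1, m=1))
        lam = lyapunov_wolf(traj, dt=1.0)
        assert lam == pytest.approx(np.log(2), abs=0.05)
        # second, independent route: average of ln|f'(x)| along the orbit
        x = logistic_series.values[:-1]
        assert np.mean(np.log(np.abs(4 - 8 * x))) == pytest.approx(np.log(2), abs=0.01)

    def test_contracting_map_gives_minus_ln2(self):
        x = 1.0 / 2 ** np.arange(50, dtype=float)
        traj = embed(TimeSeries(x, 1.0), EmbeddingParams(tau=1, m=1))
        lam = lyapunov_wolf(traj, dt=1.0, theiler=1)
        assert lam == pytest.approx(-np.log(2), abs=0.05)

    def test_periodic_orbit_neutral(self, sine_series):
        traj = embed(sine_series, EmbeddingParams(tau=15, m=2))
        assert abs(lyapunov_wolf(traj, dt=1.0)) < 0.05

    def test_invalid_dt_rejected(self, sine_series):
        traj = embed(sine_series, EmbeddingParams(tau=15, m=2))
        with pytest.raises(ValueError, match="dt"):
            lyapunov_wolf(traj, dt=0.0)


class TestSurrogates:
    def test_surrogate_preserves_amplitude_spectrum(self, rng):
        x = rng.normal(0, 1, 512)
        s = phase_randomized_surrogate(x, rng)
        np.testing.assert_allclose(np.abs(np.fft.rfft(s)), np.abs(np.fft.rfft(x)),
                                   rtol=1e-8, atol=1e-8)

    def test_logistic_nonlinearity_detected(self, logistic_series):
        """A chaotic map's Wolf exponent is bounded by the true lambda1,
        while its linear surrogates show larger spurious divergence: the
        deterministic original is extreme on the low side."""
        series = TimeSeries(logistic_series.values[:1024], 1.0)
        result = surrogate_test(series, statistic="lambda1", n_surrogates=19,
                                sided="less", seed=1, tau=1, m=1)
        assert result.rank_p <= 0.05
        assert result.original_value < result.surrogate_values.min()

    def test_ar1_null_retained(self):
        """Type-I behavior: a linear Gaussian process is rarely flagged."""
        rng = np.random.default_rng(7)
        retained = 0
        for rep in range(10):
            x = np.zeros(512)
            for i in range(1, 512):
                x[i] = 0.6 * x[i - 1] + rng.normal()
            series = TimeSeries(x, 1.0)
            result = surrogate_test(series, statistic="lambda1", n_surrogates=19,
                                    sided="less", seed=100 + rep, tau=1, m=2)
            retained += result.rank_p > 0.05
        assert retained >= 9

    def test_zero_surrogates_rejected(self, logistic_series):
        with pytest.raises(ValueError, match="n_surrogates"):
            surrogate_test(logistic_series, n_surrogates=0)

    def test_rank_p_definition(self, logistic_series):
        series = TimeSeries(logistic_series.values[:512], 1.0)
        result = surrogate_test(series, statistic="lambda1", n_surrogates=9,
                                sided="less", seed=2, tau=1, m=1)
        extreme = int(np.sum(result.surrogate_values <= result.original_value))
        assert result.rank_p == (1 + extreme) / (len(result.surrogate_values) + 1)
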