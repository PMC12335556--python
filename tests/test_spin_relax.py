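import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qebss import spin_relax as sr
from qebss.traj_io import VectorSeries
from qebss.exceptions import GridMismatchError

import oracles


def single_tau_spectrum(tau_s, weight=1.0):
    """Spectrum with all weight on one timescale (grid padded around it)."""
    grid = sr.TimescaleGrid(taus=np.array([tau_s / 10.0, tau_s, tau_s * 10.0]))
    alphas = np.array([0.0, weight, 0.0])
    return sr.TimescaleSpectrum(grid=grid, alphas=alphas)


class TestP2Acf:
    def test_constant_vector_gives_unity(self):
        v = np.tile([0.0, 0.0, 1.0], (20, 1))
        s = VectorSeries(1, 10.0 * np.arange(20), v)
        acf = sr.compute_p2_acf(s, max_lag_fraction=1.0)
        np.testing.assert_allclose(acf.values, 1.0, atol=1e-12)

    def test_perpendicular_pair_gives_minus_half(self):
        v = np.array([[0.0, 0.0, 1.0], [1.0, 0.0, 0.0]])
        s = VectorSeries(1, np.array([0.0, 10.0]), v)
        acf = sr.compute_p2_acf(s, max_lag_fraction=1.0)
        assert acf.values[1] == pytest.approx(-0.5, abs=1e-12)

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(11)
        v = rng.normal(size=(10, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        s = VectorSeries(1, 10.0 * np.arange(10), v)
        acf = sr.compute_p2_acf(s, max_lag_fraction=1.0)
        ref = oracles.brute_force_p2_acf(v, acf.lags.size)
        np.testing.assert_allclose(acf.values, ref, atol=1e-12)

    def test_lag_window_fraction(self):
        v = np.tile([0.0, 0.0, 1.0], (100, 1))
        s = VectorSeries(1, 1.0 * np.arange(100), v)
        acf = sr.compute_p2_acf(s, max_lag_fraction=0.5)
        assert acf.lags[-1] == pytest.approx(49.0)

    def test_single_frame_rejected(self):
        s = VectorSeries(1, np.array([0.0]), np.array([[0.0, 0.0, 1.0]]))
        with pytest.raises(ValueError):
            sr.compute_p2_acf(s)


class TestTimescaleGrid:
    def test_default_protocol_grid(self):
        grid = sr.build_timescale_grid()
        assert grid.n == 100
        assert grid.taus[0] == 1e-12
        assert grid.taus[-1] == 1e-7

    def test_two_point_grid_is_the_endpoints(self):
        grid = sr.build_timescale_grid(2, 1e-12, 1e-7)
        np.testing.assert_array_equal(grid.taus, [1e-12, 1e-7])

    def test_log_midpoint(self):
        grid = sr.build_timescale_grid(3, 1e-12, 1e-10)
        assert grid.taus[1] == pytest.approx(1e-11, rel=1e-12)

    def test_nonpositive_bounds_rejected(self):
        with pytest.raises(ValueError):
            sr.build_timescale_grid(10, 0.0, 1e-7)


class TestExponentialSumFit:
    def test_single_on_grid_component_recovered(self):
        grid = sr.build_timescale_grid(101, 1e-12, 1e-7)
        tau = grid.taus[60]  # exactly 1 ns on this grid
        t = 50.0 * np.arange(500)
        g = np.exp(-(t * 1e-12) / tau)
        acf = sr.CorrelationFunction(1, t, g)
        spec = sr.fit_exponential_sum(acf, grid)
        assert spec.alphas[60] >= 0.999
        others = np.delete(spec.alphas, 60)
        assert np.all(others < 1e-6)

    def test_constant_acf_concentrates_on_slowest_tau(self):
        grid = sr.build_timescale_grid(20, 1e-12, 1e-9)
        t = 50.0 * np.arange(200)
        acf = sr.CorrelationFunction(1, t, np.ones_like(t))
        spec = sr.fit_exponential_sum(acf, grid)
        assert np.argmax(spec.alphas) == grid.n - 1
        # single-column least squares on the slowest exponential
        col = np.exp(-(t * 1e-12) / grid.taus[-1])
        alpha = max(0.0, float(col @ np.ones_like(t) / (col @ col)))
        ref_residual = np.linalg.norm(np.ones_like(t) - alpha * col)
        assert spec.fit_residual <= ref_residual + 1e-9

    def test_all_nan_acf_rejected(self):
        t = 10.0 * np.arange(5)
        acf = sr.CorrelationFunction(1, t, np.array([1.0] + [np.nan] * 4))
        with pytest.raises(ValueError):
            sr.fit_exponential_sum(acf)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(
        w=st.floats(0.05, 0.95),
        i1=st.integers(40, 60),
        i2=st.integers(65, 90),
    )
    def test_noiseless_grid_acf_is_reproduced_at_all_lags(self, w, i1, i2):
        grid = sr.build_timescale_grid()
        t = 100.0 * np.arange(400)
        taus = np.array([grid.taus[i1], grid.taus[i2]])
        weights = np.array([w, 1.0 - w])
        g = (weights * np.exp(-(t[:, None] * 1e-12) / taus)).sum(axis=1)
        acf = sr.CorrelationFunction(1, t, g)
        spec = sr.fit_exponential_sum(acf, grid)
        np.testing.assert_allclose(spec.evaluate(t * 1e-12), g, atol=1e-9)


class TestSpectralDensity:
    def test_zero_frequency_lorentzian(self):
        spec = single_tau_spectrum(5e-9)
        assert sr.spectral_density(spec, 0.0) == pytest.approx(1e-8)

    def test_half_height_at_inverse_tau(self):
        tau = 5e-9
        spec = single_tau_spectrum(tau)
        assert sr.spectral_density(spec, 1.0 / tau) == pytest.approx(tau)

    def test_linearity_over_components(self):
        grid = sr.build_timescale_grid(10, 1e-12, 1e-8)
        rng = np.random.default_rng(3)
        alphas = rng.uniform(0, 0.3, 10)
        spec = sr.TimescaleSpectrum(grid=grid, alphas=alphas)
        for omega in (0.0, 1e8, 5e9):
            expected = sum(
                a * 2 * tau / (1 + (omega * tau) ** 2)
                for a, tau in zip(alphas, grid.taus)
            )
            assert sr.spectral_density(spec, omega) == pytest.approx(
                expected, rel=1e-15
            )

    def test_even_in_frequency(self):
        spec = single_tau_spectrum(2e-9)
        assert sr.spectral_density(spec, -3e8) == sr.spectral_density(spec, 3e8)


class TestRelaxationObservables:
    @pytest.mark.parametrize("field_mhz", [600.0, 800.0, 850.0])
    @pytest.mark.parametrize("tau", [10e-12, 1e-9, 5e-9, 20e-9])
    def test_matches_closed_form_oracle(self, tau, field_mhz):
        spec = single_tau_spectrum(tau)
        params = sr.NMRParams(field_mhz=field_mhz)
        mine = sr.relaxation_observables(spec, params)
        ref = oracles.closed_form_redfield(tau, field_mhz)
        for m, r in zip(mine, ref):
            assert m == pytest.approx(r, rel=1e-10)

    def test_extreme_narrowing_t1_equals_t2(self):
        spec = single_tau_spectrum(1e-12)
        t1, t2, _ = sr.relaxation_observables(
            spec, sr.NMRParams(field_mhz=600.0, delta_sigma_ppm=0.0)
        )
        assert t1 / t2 == pytest.approx(1.0, rel=0.01)

    def test_extreme_narrowing_noe_limit_dipolar_only(self):
        spec = single_tau_spectrum(1e-12)
        params = sr.NMRParams(field_mhz=600.0, delta_sigma_ppm=0.0)
        _, _, noe = sr.relaxation_observables(spec, params)
        expected = 1.0 + 0.5 * params.gamma_h / params.gamma_n
        assert noe == pytest.approx(expected, rel=0.01)

    def test_noe_sign_conventions_hit_their_analytic_limits(self):
        # extreme narrowing, dipolar-only: sigma*T1 = 5J/10J = 1/2 for the
        # standard 6J(wH+wN) - J(wH-wN) convention, 7J/10J = 7/10 for the
        # all-plus variant
        spec = single_tau_spectrum(1e-12)
        base = dict(field_mhz=600.0, delta_sigma_ppm=0.0)
        minus = sr.relaxation_observables(spec, sr.NMRParams(**base))[2]
        plus = sr.relaxation_observables(
            spec,
            sr.NMRParams(**base, noe_sign_convention="paper_plus"),
        )[2]
        gamma_ratio = sr.GAMMA_H / sr.GAMMA_N
        assert minus == pytest.approx(1.0 + 0.5 * gamma_ratio, rel=1e-3)
        assert plus == pytest.approx(1.0 + 0.7 * gamma_ratio, rel=1e-3)

    def test_t2_decreases_as_weight_moves_to_slow_tau(self):
        grid = sr.build_timescale_grid(10, 1e-12, 1e-7)
        params = sr.NMRParams(field_mhz=600.0, delta_sigma_ppm=0.0)
        t2s = []
        for w_slow in np.linspace(0.0, 1.0, 6):
            alphas = np.zeros(10)
            alphas[0] = 1.0 - w_slow
            alphas[-1] = w_slow
            if alphas.sum() == 0:
                continue
            t2s.append(sr.relaxation_observables(
                sr.TimescaleSpectrum(grid=grid, alphas=alphas), params
            )[1])
        assert all(a >= b for a, b in zip(t2s, t2s[1:]))

    def test_zero_field_rejected(self):
        with pytest.raises(ValueError):
            sr.NMRParams(field_mhz=0.0)


class TestEffectiveTau:
    def test_single_component(self):
        assert sr.effective_tau(single_tau_spectrum(5e-9)) == pytest.approx(5e-9)

    def test_weighted_sum(self):
        grid = sr.TimescaleGrid(taus=np.array([1e-9, 1e-8]))
        spec = sr.TimescaleSpectrum(grid=grid, alphas=np.array([0.3, 0.7]))
        assert sr.effective_tau(spec) == pytest.approx(7.3e-9)

    def test_zero_weights(self):
        grid = sr.TimescaleGrid(taus=np.array([1e-9, 1e-8]))
        spec = sr.TimescaleSpectrum(grid=grid, alphas=np.zeros(2))
        assert sr.effective_tau(spec) == 0.0


class TestAverageAcfs:
    def _acf(self, tau_ps, rid=4, n=50):
        t = 10.0 * np.arange(n)
        return sr.CorrelationFunction(rid, t, np.exp(-t / tau_ps))

    def test_average_of_one_is_identity(self):
        a = self._acf(100.0)
        avg = sr.average_acfs([a])
        np.testing.assert_array_equal(avg.values, a.values)

    def test_idempotent_on_duplicates(self):
        a = self._acf(100.0)
        avg = sr.average_acfs([a, a])
        np.testing.assert_allclose(avg.values, a.values, rtol=1e-15)
        assert avg.n_contributing == 2

    def test_pointwise_mean_of_two_decays(self):
        a, b = self._acf(100.0), self._acf(400.0)
        avg = sr.average_acfs([a, b])
        np.testing.assert_allclose(avg.values, (a.values + b.values) / 2,
                                   rtol=1e-15)

    def test_truncates_to_shortest(self):
        a, b = self._acf(100.0, n=50), self._acf(100.0, n=30)
        assert sr.average_acfs([a, b]).lags.size == 30

    def test_residue_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            sr.average_acfs([self._acf(100.0, rid=4), self._acf(100.0, rid=5)])


class TestTimescaleLandscape:
    def test_single_component_lands_in_its_bin(self):
        spec = single_tau_spectrum(5e-9)
        _, w = sr.timescale_landscape([spec], np.array([2e-9, 6e-9, 12e-9]))
        np.testing.assert_allclose(w, [[1.0, 0.0]])

    def test_split_weights_reported_per_bin(self):
        grid = sr.TimescaleGrid(taus=np.array([4e-9, 8e-9]))
        spec = sr.TimescaleSpectrum(grid=grid, alphas=np.array([0.75, 0.25]))
        _, w = sr.timescale_landscape([spec], np.array([2e-9, 6e-9, 12e-9]))
        np.testing.assert_allclose(w, [[0.75, 0.25]])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=100, max_size=100))
    def test_bins_conserve_total_weight(self, alphas):
        grid = sr.build_timescale_grid()
        spec = sr.TimescaleSpectrum(grid=grid, alphas=np.array(alphas))
        edges = np.array([0.5e-12, 2e-9, 6e-9, 12e-9, 2e-7])
        _, w = sr.timescale_landscape([spec], edges)
        assert w.sum() == pytest.approx(spec.total_weight, abs=1e-12)

    def test_empty_spectra_rejected(self):
        with pytest.raises(ValueError):
            sr.timescale_landscape([], np.array([1e-12, 1e-7]))
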