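import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gridheat import (
    HoleyFilmPattern,
    ParameterError,
    SolverError,
    ThermalParams,
    node_source,
    peak_temperature,
    steady_1d,
    steady_2d,
    transient_2d,
)

# Peak of the unit-square Poisson problem −∇²u = 1, u|∂ = 0, from the
# classical double Fourier series 16/π⁴·ΣΣ sin(mπ/2)sin(nπ/2)/(mn(m²+n²))
# over odd m, n (truncated at 2000 terms each; truncation error ≪ 1e-9).
POISSON_UNIT_SQUARE_PEAK = 0.07367135326539


def fd_solve_1d(P, alpha, L, T0, n):
    """Independent finite-difference oracle for d²T/dx² = −Pα, T(0)=T(L)=T0."""
    h = L / (n - 1)
    m = n - 2
    A = np.diag(np.full(m, -2.0)) + np.diag(np.ones(m - 1), 1) + np.diag(np.ones(m - 1), -1)
    rhs = np.full(m, -P * alpha * h**2)
    interior = np.linalg.solve(A, rhs)
    return np.concatenate([[0.0], interior, [0.0]]) + T0


class TestThermalParams:
    def test_defaults_are_cryostage_conditions(self):
        th = ThermalParams()
        assert th.T0 == 77.0 and th.Tmax == 136.0

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ParameterError):
            ThermalParams(T0=140.0, Tmax=136.0)


class TestSteady1D:
    def test_no_source_stays_at_base_temperature(self):
        field = steady_1d(0.0, 2e-3, 58.0)
        assert np.all(field.values == 77.0)

    @given(P=st.floats(0.0, 500.0))
    def test_boundaries_pinned_at_T0(self, P):
        field = steady_1d(P, 2e-3, 58.0)
        assert field.values[0] == 77.0 and field.values[-1] == 77.0
        assert np.all(field.values >= 77.0)

    def test_matches_finite_difference_oracle(self):
        P, alpha, L, T0, n = 64.0, 2.193e-3, 58.0, 77.0, 257
        field = steady_1d(P, alpha, L, T0, n_points=n)
        oracle = fd_solve_1d(P, alpha, L, T0, n)
        assert np.max(np.abs(field.values - oracle)) < 1e-9 * field.rise

    def test_negative_power_rejected(self):
        with pytest.raises(ParameterError):
            steady_1d(-1.0, 2e-3, 58.0)


class TestPeakTemperature:
    def test_quadratic_in_square_size(self):
        rise = peak_temperature(10.0, 2e-3, 58.0) - 77.0
        rise2 = peak_temperature(10.0, 2e-3, 116.0) - 77.0
        assert rise2 == pytest.approx(4 * rise, rel=1e-12)

    def test_linear_in_power(self):
        rise = peak_temperature(10.0, 2e-3, 58.0) - 77.0
        rise2 = peak_temperature(20.0, 2e-3, 58.0) - 77.0
        assert rise2 == pytest.approx(2 * rise, rel=1e-12)

    def test_alpha_calibrated_at_devitrification_point(self):
        # α making the 300-mesh square peak exactly at 136 K under 64 W/cm²
        alpha = 8 * (136 - 77) / (64 * 58**2)
        assert alpha == pytest.approx(2.193e-3, rel=1e-3)
        assert peak_temperature(64.0, alpha, 58.0, 77.0) == pytest.approx(136.0, rel=1e-12)


class TestSteady2D:
    def test_uniform_source_unit_square_matches_series_oracle(self):
        n = 129
        field = steady_2d(np.ones((n, n)), 1.0, 1.0, 1.0, T0=0.0)
        assert field.peak_T == pytest.approx(POISSON_UNIT_SQUARE_PEAK, abs=1e-4)

    def test_peak_error_shrinks_quadratically_under_refinement(self):
        errs = []
        for n in (33, 65, 129):
            field = steady_2d(np.ones((n, n)), 1.0, 1.0, 1.0, T0=0.0)
            errs.append(abs(field.peak_T - POISSON_UNIT_SQUARE_PEAK))
        ratios = [errs[0] / errs[1], errs[1] / errs[2]]
        assert all(3.0 < r < 5.0 for r in ratios)

    def test_symmetric_source_gives_symmetric_field(self, rng):
        n = 65
        half = rng.uniform(0.0, 5.0, size=(n, (n + 1) // 2))
        source = np.concatenate([half, half[:, -2::-1]], axis=1)
        field = steady_2d(source, 1e-3, 30.0, 30.0)
        assert np.max(np.abs(field.values - field.values[:, ::-1])) < 1e-10

    def test_maximum_principle(self, rng):
        n = 49
        source = rng.uniform(0.0, 10.0, size=(n, n))
        field = steady_2d(source, 1e-3, 20.0, 20.0, T0=77.0)
        assert field.values.min() == 77.0
        assert np.all(field.values[1:-1, 1:-1] > 77.0)

    def test_superposition(self, rng):
        n = 49
        q1 = rng.uniform(0.0, 5.0, size=(n, n))
        q2 = rng.uniform(0.0, 5.0, size=(n, n))
        f1 = steady_2d(q1, 1e-3, 20.0, 20.0, T0=0.0)
        f2 = steady_2d(q2, 1e-3, 20.0, 20.0, T0=0.0)
        f12 = steady_2d(q1 + q2, 1e-3, 20.0, 20.0, T0=0.0)
        assert np.max(np.abs(f12.values - f1.values - f2.values)) < 1e-9 * f12.rise

    def test_long_strip_recovers_1d_profile(self):
        # y-invariant source on a 10:1 strip: the central row is the 1D slab
        Lx, res = 10.0, 3.3
        Ly = 10 * Lx
        nx, ny = int(round(Lx * res)) + 1, int(round(Ly * res)) + 1
        field2 = steady_2d(np.full((ny, nx), 5.0), 2e-3, Lx, Ly, T0=77.0)
        field1 = steady_1d(5.0, 2e-3, Lx, 77.0, n_points=nx)
        dev = np.max(np.abs(field2.values[(ny - 1) // 2] - field1.values))
        assert dev < 0.01 * field1.rise

    def test_too_coarse_raster_rejected(self):
        with pytest.raises(ParameterError):
            steady_2d(np.ones((10, 10)), 1.0, 1.0, 1.0)

    def test_negative_source_rejected(self):
        with pytest.raises(ParameterError):
            steady_2d(-np.ones((40, 40)), 1.0, 1.0, 1.0)


class TestNodeSource:
    def test_supersampled_mask_mean_close_to_eta(self):
        pattern = HoleyFilmPattern(2.0, 1.0)
        src = node_source(pattern, 64.0, 58.0, 4.0)
        from gridheat import carbon_area_fraction

        assert src.mean() / 64.0 == pytest.approx(carbon_area_fraction(pattern), rel=0.02)

    def test_continuous_film_uniform_beam_is_constant(self):
        src = node_source(HoleyFilmPattern.continuous(), 10.0, 20.0, 2.0)
        assert np.all(src == 10.0)


class TestTransient2D:
    def setup_method(self):
        self.n = 41
        self.source = np.full((self.n, self.n), 10.0)
        self.kwargs = dict(alpha_eff=1e-3, Lx=20.0, Ly=20.0, T0=77.0)

    def test_zero_source_stays_at_base(self):
        fields = transient_2d(np.zeros((self.n, self.n)), 1e-3, 1.0, dt=1.0, t_end=10.0,
                              Lx=20.0, Ly=20.0, T0=77.0)
        assert np.all(fields[-1].values == 77.0)

    def test_converges_to_steady_state(self):
        steady = steady_2d(self.source, **self.kwargs)
        fields = transient_2d(self.source, heat_capacity_scale=1.0, dt=0.5, t_end=1500.0,
                              store_every=3000, **self.kwargs)
        dev = np.max(np.abs(fields[-1].values - steady.values))
        assert dev < 1e-6 * steady.rise

    def test_monotone_heating_from_base_temperature(self):
        fields = transient_2d(self.source, heat_capacity_scale=1.0, dt=2.0, t_end=40.0,
                              **self.kwargs)
        for a, b in zip(fields, fields[1:]):
            assert np.all(b.values >= a.values - 1e-12)

    def test_time_step_convergence(self):
        final = [
            transient_2d(self.source, heat_capacity_scale=1.0, dt=dt, t_end=1200.0,
                         store_every=10**6, **self.kwargs)[-1]
            for dt in (1.0, 0.5)
        ]
        steady = steady_2d(self.source, **self.kwargs)
        dev = np.max(np.abs(final[0].values - final[1].values))
        assert dev < 1e-6 * steady.rise

    def test_explicit_scheme_matches_implicit(self):
        kw = dict(heat_capacity_scale=1.0, t_end=600.0, store_every=10**7)
        h = 20.0 / (self.n - 1)
        dt_stable = 1.0 / (2 * (2 / h**2))
        imp = transient_2d(self.source, dt=dt_stable, scheme="implicit", **kw, **self.kwargs)[-1]
        exp = transient_2d(self.source, dt=dt_stable, scheme="explicit", **kw, **self.kwargs)[-1]
        assert np.max(np.abs(imp.values - exp.values)) < 1e-3 * imp.rise

    def test_unstable_explicit_step_rejected_naming_bound(self):
        with pytest.raises(ParameterError, match="stable bound"):
            transient_2d(self.source, heat_capacity_scale=1.0, dt=10.0, t_end=100.0,
                         scheme="explicit", **self.kwargs)
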