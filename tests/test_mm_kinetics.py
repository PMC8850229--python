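import numpy as np
import pytest
from hypothesis import given, strategies as st

from kmdkit import (
    ConcentrationSeries,
    MMParams,
    analytic_concentration,
    conc_at_fraction,
    elimination_span,
    interval_slopes,
    mm_rate,
    simulate_elimination,
)

positive = st.floats(min_value=1e-3, max_value=1e3, allow_nan=False)


class TestMMRate:
    @pytest.mark.parametrize(
        "s, vmax, km, expected",
        [
            (0.0, 25.0, 10.5, 0.0),
            (10.5, 25.0, 10.5, 12.5),  # s = Km gives half-maximal rate
            (199.5, 25.0, 10.5, 25 * 199.5 / 210),
        ],
    )
    def test_known_values(self, s, vmax, km, expected):
        assert mm_rate(s, MMParams(vmax, km)) == pytest.approx(expected, rel=1e-12)

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            mm_rate(-1.0, MMParams(25, 10.5))

    @given(vmax=positive, km=positive)
    def test_monotone_increasing_and_bounded(self, vmax, km):
        p = MMParams(vmax, km)
        s = np.linspace(0, 50 * km, 200)
        v = mm_rate(s, p)
        assert np.all(np.diff(v) > 0)
        assert np.all(v < vmax)
        assert v[0] == 0.0


class TestConcAtFraction:
    @pytest.mark.parametrize(
        "fraction, km, expected",
        [
            (0.95, 1.0, 19.0),
            (0.90, 1.0, 9.0),
            (0.90, 11.8, 106.2),
            (0.95, 11.8, 224.2),
            (0.5, 7.0, 7.0),
        ],
    )
    def test_fractional_vmax_algebra(self, fraction, km, expected):
        assert conc_at_fraction(fraction, km) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.5, 1.5])
    def test_fraction_domain(self, bad):
        with pytest.raises(ValueError):
            conc_at_fraction(bad, 10.0)

    @given(f=st.floats(min_value=0.01, max_value=0.99), km=positive)
    def test_ratio_to_km_depends_only_on_fraction(self, f, km):
        assert conc_at_fraction(f, km) / km == pytest.approx(
            conc_at_fraction(f, 1.0), rel=1e-9
        )


class TestAnalyticVsNumeric:
    def test_initial_condition(self):
        p = MMParams(25, 10.5)
        assert analytic_concentration(199.5, p, 0.0) == pytest.approx(199.5, rel=1e-12)

    def test_zero_c0_stays_zero(self):
        p = MMParams(25, 10.5)
        out = analytic_concentration(0.0, p, np.linspace(0, 5, 7))
        assert np.all(out == 0.0)
        sim = simulate_elimination(0.0, p, np.linspace(0, 5, 7))
        assert np.all(sim.concentrations == 0.0)

    def test_matches_ode_solver(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            vmax = 10 ** rng.uniform(0, 2.3)
            km = 10 ** rng.uniform(0, 2.3)
            p = MMParams(vmax, km)
            c0 = rng.uniform(2, 25) * km
            times = np.linspace(0, elimination_span(p, c0, remaining=0.01), 40)
            sim = simulate_elimination(c0, p, times)
            exact = analytic_concentration(c0, p, times)
            assert np.max(np.abs(sim.concentrations - exact) / exact) < 1e-6

    def test_first_order_limit(self):
        # well below Km elimination is first-order with rate constant Vmax/Km
        p = MMParams(25, 10.5)
        c0 = p.km / 1000
        t = np.linspace(0, 2 * p.km / p.vmax, 20)
        exact = analytic_concentration(c0, p, t)
        first_order = c0 * np.exp(-p.vmax * t / p.km)
        # the first-order approximation is itself accurate only to O(c0/km)
        assert np.allclose(exact, first_order, rtol=2e-3)

    def test_underflow_returns_zero_with_warning(self):
        p = MMParams(25, 10.5)
        with pytest.warns(RuntimeWarning):
            out = analytic_concentration(100.0, p, 1e6)
        assert out == 0.0

    def test_noiseless_simulation_strictly_decreasing(self):
        p = MMParams(175, 11.8)
        times = np.linspace(0, elimination_span(p, 224.2), 49)
        sim = simulate_elimination(224.2, p, times)
        assert np.all(np.diff(sim.concentrations) < 0)


class TestIntervalSlopes:
    def test_constant_series_has_zero_slopes(self):
        s = ConcentrationSeries(np.arange(5.0), np.full(5, 3.0))
        assert all(sl == 0.0 for _, sl in interval_slopes(s, 1.0))

    def test_incommensurate_dt_rejected(self):
        s = ConcentrationSeries(np.arange(5.0), np.full(5, 3.0))
        with pytest.raises(ValueError):
            interval_slopes(s, 0.7)

    @pytest.mark.parametrize(
        "vmax, km, frac, interval, expected",
        [
            (25, 10.5, 0.95, 0, -23.71),
            (25, 10.5, 0.95, 19, -4.65),
            (100, 100, 0.95, 0, -94.94),
            (100, 100, 0.90, 0, -89.77),
        ],
    )
    def test_printed_slope_table_spot_values(self, table1_grid, vmax, km, frac, interval, expected):
        p = MMParams(vmax, km)
        c0 = conc_at_fraction(frac, km)
        sim = simulate_elimination(c0, p, table1_grid)
        slopes = interval_slopes(sim, 0.5)
        assert slopes[interval][1] == pytest.approx(expected, abs=0.01)

    def test_slope_magnitude_decreases_over_time(self, table1_grid):
        p = MMParams(25, 10.5)
        sim = simulate_elimination(conc_at_fraction(0.95, p.km), p, table1_grid)
        mags = [abs(sl) for _, sl in interval_slopes(sim, 0.5)]
        assert all(a >= b - 1e-12 for a, b in zip(mags[:-1], mags[1:]))

    def test_early_slope_near_zero_order(self):
        # starting at 19*Km (95% of Vmax) the initial slope is near -Vmax
        p = MMParams(25, 10.5)
        sim = simulate_elimination(19 * p.km, p, np.array([0.0, 0.5]))
        (_, slope), = interval_slopes(sim, 0.5)
        assert abs(slope + p.vmax) / p.vmax < 0.053


class TestValidation:
    @pytest.mark.parametrize("vmax, km", [(0, 1), (-1, 1), (1, 0), (1, -2), (np.inf, 1)])
    def test_mm_params_invariants(self, vmax, km):
        with pytest.raises(ValueError):
            MMParams(vmax, km)

    def test_series_times_must_increase(self):
        with pytest.raises(ValueError):
            ConcentrationSeries(np.array([0.0, 1.0, 1.0]), np.ones(3))

    def test_series_negative_concentration(self):
        with pytest.raises(ValueError):
            ConcentrationSeries(np.arange(3.0), np.array([1.0, -0.1, 0.0]))
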