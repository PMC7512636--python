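"""Deterministic core: first integral, orbits, periods, averaging weights."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad, solve_ivp

import pulselv as pl
from pulselv.model_core import exponential_delay_kernel, period_integrals


@pytest.mark.parametrize(
    "a1, s, c, f, expected",
    [(0.9, 0.0, 0.5, 0.5, 0.9),       # no self-competition: a = a1
     (1.0, 0.2, 0.5, 0.5, 0.8)],
)
def test_reduced_growth_rate(a1, s, c, f, expected):
    assert pl.derive_reduced_growth(a1, s, c, f) == pytest.approx(expected)


def test_reduced_growth_rejects_overdamped():
    with pytest.raises(ValueError, match="equilibrium"):
        pl.derive_reduced_growth(0.1, 2.0, 0.5, 0.5)


@pytest.mark.parametrize(
    "a, b, c, f, eq",
    [(0.9, 1.0, 0.5, 0.5, (1.0, 0.9)),
     (1.0, 1.0, 1.0, 1.0, (1.0, 1.0)),
     (0.9, 0.9, 2.0, 1.0, (2.0, 1.0))],
)
def test_equilibrium(a, b, c, f, eq):
    p = pl.ModelParams(a=a, b=b, c=c, f=f, eps=0.1, s=20.0, gamma=10.0)
    assert pl.equilibrium(p) == pytest.approx(eq)


class TestFirstIntegral:
    def test_zero_at_equilibrium(self, fig1_params, fig2_params):
        for p in (fig1_params, fig2_params):
            assert abs(pl.first_integral(pl.equilibrium(p), p)) < 1e-14

    def test_term_by_term_value(self, fig1_params):
        # independent term-by-term evaluation at (2.0, 0.9)
        a, b, c, f = 0.9, 1.0, 0.5, 0.5
        e4sg = 0.2 * 0.2  # (eps^2 s)(eps^2 gamma)
        expected = (f * 2.0 - c - c * np.log(f * 2.0 / c)
                    + b * 0.9 - a - a * np.log(b * 0.9 / a)
                    - e4sg * c * 2.0 + 0.5 * e4sg * f * 4.0
                    + e4sg * c**2 / (2 * f))
        assert pl.first_integral((2.0, 0.9), fig1_params) == pytest.approx(
            expected, abs=1e-15)
        assert expected == pytest.approx(0.1634, abs=5e-5)

    def test_classical_limit_without_delay_or_competition(self):
        p = pl.ModelParams(a=0.9, b=1.0, c=0.5, f=0.5, eps=0.1)
        x1, x2 = 1.7, 0.4
        classical = (0.5 * x1 - 0.5 - 0.5 * np.log(0.5 * x1 / 0.5)
                     + x2 - 0.9 - 0.9 * np.log(x2 / 0.9))
        assert pl.first_integral((x1, x2), p) == pytest.approx(classical)

    def test_rejects_nonpositive_coordinates(self, fig1_params):
        with pytest.raises(ValueError):
            pl.first_integral((0.0, 1.0), fig1_params)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(x1=st.floats(0.05, 8.0), x2=st.floats(0.05, 8.0))
    def test_nonnegative_everywhere(self, x1, x2):
        p = pl.ModelParams(a=0.9, b=1.0, c=0.5, f=0.5, eps=0.1,
                           s=20.0, gamma=20.0)
        assert pl.first_integral((x1, x2), p) >= -1e-12


class TestDrifts:
    def test_equilibrium_is_fixed_point(self, fig1_params):
        eq = pl.equilibrium(fig1_params)
        assert pl.conservative_drift(eq, fig1_params) == pytest.approx((0, 0))
        assert pl.reduced_drift(eq, fig1_params) == pytest.approx((0, 0))

    def test_conservative_drift_value(self, fig1_params):
        # on the line x2 = a/b the prey velocity vanishes
        d1, d2 = pl.conservative_drift((2.0, 0.9), fig1_params)
        assert d1 == pytest.approx(0.0)
        assert d2 == pytest.approx(0.9 * 0.5 * (1 + 0.04 * 2.0))

    def test_reduced_minus_conservative_is_delay_and_competition(self, fig1_params):
        p = fig1_params
        rng = np.random.default_rng(0)
        for _ in range(10):
            x1, x2 = rng.uniform(0.2, 3.0, 2)
            r1, r2 = pl.reduced_drift((x1, x2), p)
            c1, c2 = pl.conservative_drift((x1, x2), p)
            e2 = p.eps**2
            assert r1 - c1 == pytest.approx(
                -x1 * e2 * p.s / p.f * (p.f * x1 - p.c), rel=1e-12)
            assert r2 - c2 == pytest.approx(
                x2 * e2 * p.f * p.gamma * x1 * (p.b * x2 - p.a), rel=1e-12)

    def test_classical_limit(self):
        p = pl.ModelParams(a=0.9, b=1.0, c=0.5, f=0.5, eps=0.1)
        d = pl.reduced_drift((1.3, 0.7), p)
        assert d == pytest.approx((1.3 * (0.9 - 0.7), 0.7 * (-0.5 + 0.5 * 1.3)))

    def test_first_integral_conserved_along_flow(self, fig1_params):
        sol = solve_ivp(
            lambda t, y: pl.conservative_drift(y, fig1_params),
            (0, 30.0), [2.0, 0.9], rtol=1e-10, atol=1e-10, dense_output=True)
        r = pl.first_integral((sol.y[0], sol.y[1]), fig1_params)
        assert np.max(np.abs(r - r[0])) < 1e-8


class TestOrbits:
    @pytest.mark.parametrize("K", [0.892, 1.146, 1.565])
    def test_closure_and_conservation(self, fig1_params, K):
        orb = pl.find_orbit(K, fig1_params, ivp_tol=1e-10)
        assert orb.max_level_error() < 1e-6
        assert orb.closure_gap() == 0.0  # stored polyline closes exactly
        assert orb.times[0] == 0.0 and orb.times[-1] == orb.period
        assert np.all(np.diff(orb.times) > 0)
        # the middle orbit surrounds the equilibrium
        assert orb.x1.min() < fig1_params.x10 < orb.x1.max()
        assert orb.x2.min() < fig1_params.x20 < orb.x2.max()

    def test_degenerate_level_collapses_to_equilibrium(self, fig1_params):
        orb = pl.find_orbit(1e-5, fig1_params)
        eq = np.array(pl.equilibrium(fig1_params))
        assert np.max(np.hypot(*(orb.points - eq).T)) < 0.01

    def test_rejects_level_above_maximum(self, fig1_params):
        with pytest.raises(ValueError, match="maximum level"):
            pl.find_orbit(2.0, fig1_params, max_K=1.0)

    def test_period_forms_agree(self, fig1_params):
        for K in (0.05, 0.5, 1.565, 2.0):
            T_ret = pl.period(K, fig1_params)
            T1, T2 = period_integrals(K, fig1_params)
            assert T1 == pytest.approx(T_ret, rel=1e-4)
            assert T2 == pytest.approx(T_ret, rel=1e-4)

    def test_period_grows_with_level(self, fig1_params):
        assert pl.period(1.565, fig1_params) > pl.period(0.892, fig1_params)

    def test_harmonic_limit(self, fig1_params):
        T0 = pl.harmonic_period(fig1_params)
        p = fig1_params
        assert T0 == pytest.approx(
            2 * np.pi / np.sqrt(p.a * p.c * (1 + 0.04 * p.c / p.f)))
        errs = [abs(pl.period(K, p) - T0) for K in (0.02, 0.01, 0.005)]
        assert errs[0] < 0.05 * T0
        # error shrinks at least linearly in K
        assert errs[1] < 0.75 * errs[0]
        assert errs[2] < 0.75 * errs[1]


class TestOrbitAverage:
    def test_normalization(self, fig1_params):
        orb = pl.find_orbit(0.892, fig1_params)
        assert pl.orbit_average(orb, lambda x1, x2: np.ones_like(x1)) == \
            pytest.approx(1.0, abs=1e-12)

    def test_time_derivatives_average_to_zero(self, fig1_params):
        # d(ln x1)/dt and d(ln x2)/dt integrate to zero over one period
        p = fig1_params
        orb = pl.find_orbit(1.146, p)
        g1 = pl.orbit_average(orb, lambda x1, x2: p.a - p.b * x2)
        g2 = pl.orbit_average(
            orb, lambda x1, x2: (p.f * x1 - p.c) * (1 + p.eps4_s_gamma * x1))
        assert abs(g1) < 1e-6
        assert abs(g2) < 1e-6


def test_exponential_kernel_normalized_with_mean_gamma():
    for g in (0.5, 1.0, 2.0):
        mass, _ = quad(lambda t: exponential_delay_kernel(t, g), 0, np.inf)
        mean, _ = quad(lambda t: t * exponential_delay_kernel(t, g), 0, np.inf)
        assert mass == pytest.approx(1.0, abs=1e-10)
        assert mean == pytest.approx(g, rel=1e-8)


def test_caption_and_raw_constructors_agree():
    p1 = pl.ModelParams.from_caption(0.1, 0.9, 1.0, 0.5, 0.5, 0.2, 0.2)
    p2 = pl.ModelParams.from_rates(a1=0.9 + 0.2 * 0.5 / 0.5, s_phys=0.2,
                                   b=1.0, c=0.5, f=0.5, gamma_phys=0.2, eps=0.1)
    assert p1.a == pytest.approx(p2.a)
    assert p1.s == pytest.approx(p2.s)
    assert p1.gamma == pytest.approx(p2.gamma)
    assert p1.eps2_s == pytest.approx(0.2)
    assert p1.a1 == pytest.approx(1.1)


def test_large_eps_warns():
    with pytest.warns(UserWarning, match="eps"):
        pl.ModelParams(a=1.0, b=1.0, c=1.0, f=1.0, eps=0.7)
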