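"""Monte Carlo simulators: jump schemes, Gaussian limit, delay validator."""

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp

import pulselv as pl
from pulselv import simulate
from pulselv.simulate import SimConfig


@pytest.fixture(scope="module")
def short_cfg():
    return SimConfig(t_max=2000.0, dt=5e-3, n_samples=1, burn_in=100.0, seed=7)


class TestSimConfig:
    def test_validation(self):
        with pytest.raises(ValueError, match="scheme"):
            SimConfig(scheme="euler")
        with pytest.raises(ValueError, match="burn_in"):
            SimConfig(t_max=10.0, burn_in=20.0)

    def test_thinning_bounds_storage(self):
        cfg = SimConfig(t_max=5e4, dt=5e-3, max_stored=1_000_000)
        assert cfg.thin == 10


class TestPoisson:
    def test_seeded_reproducibility(self, fig2_params, fig2_noise, short_cfg):
        a = simulate.simulate_poisson(fig2_params, fig2_noise, short_cfg)
        b = simulate.simulate_poisson(fig2_params, fig2_noise, short_cfg)
        np.testing.assert_array_equal(a.x1, b.x1)
        np.testing.assert_array_equal(a.x2, b.x2)
        pd.testing.assert_frame_equal(a.pulses, b.pulses)

    def test_positivity(self, fig2_params, fig2_noise, short_cfg):
        tr = simulate.simulate_poisson(fig2_params, fig2_noise, short_cfg)
        assert np.all(tr.x1 > 0)
        assert np.all(tr.x2 > 0)

    def test_pulse_statistics(self, fig2_params, fig2_noise):
        cfg = SimConfig(t_max=20000.0, dt=5e-3, n_samples=1, burn_in=0, seed=9)
        tr = simulate.simulate_poisson(fig2_params, fig2_noise, cfg)
        tr.check_pulse_statistics(fig2_noise)
        amp = tr.pulses["amplitude"].to_numpy()
        n = amp.size
        se2 = np.sqrt(2.0) * fig2_noise.EY2_1 / np.sqrt(n)  # var-of-variance SE
        assert abs(amp.mean()) < 5 * np.sqrt(fig2_noise.EY2_1 / n)
        assert abs(amp.var() - fig2_noise.EY2_1) < 6 * se2

    def test_conservative_limit_without_noise(self):
        # s = gamma = 0 and no pulses: the classical invariant is conserved
        p = pl.ModelParams(a=0.9, b=1.0, c=0.5, f=0.5, eps=0.1)
        silent = pl.NoiseSpec(0.0, 0.0, 1.0, 1.0)
        cfg = SimConfig(t_max=50.0, dt=1e-3, n_samples=1, burn_in=0, seed=0,
                        initial=pl.Point(2.0, 0.9))
        tr = simulate.simulate_poisson(p, silent, cfg)
        r = pl.first_integral((tr.x1, tr.x2), p)
        assert np.max(np.abs(r - r[0])) < 1e-9

    def test_jump_rule_is_multiplicative_exponential(self, fig2_params):
        # a single rare prey pulse: X1 jumps by e^{eps Y}, X2 continuously
        noise = pl.NoiseSpec(0.02, 0.0, 5.0, 1.0)
        cfg = SimConfig(t_max=400.0, dt=1e-3, n_samples=1, burn_in=0, seed=12)
        tr = simulate.simulate_poisson(fig2_params, noise, cfg)
        assert len(tr.pulses) >= 1
        t_p = tr.pulses["t"].iloc[0]
        y = tr.pulses["amplitude"].iloc[0]
        i_pre = np.searchsorted(tr.times, t_p) - 1
        i_post = i_pre + 1
        # integrate the noise-free drift across the same window as a reference
        sol = solve_ivp(lambda t, z: pl.reduced_drift(z, fig2_params),
                        (tr.times[i_pre], t_p),
                        [tr.x1[i_pre], tr.x2[i_pre]], rtol=1e-12, atol=1e-12)
        x1_pre, x2_pre = sol.y[:, -1]
        sol2 = solve_ivp(lambda t, z: pl.reduced_drift(z, fig2_params),
                         (t_p, tr.times[i_post]),
                         [x1_pre * np.exp(fig2_params.eps * y), x2_pre],
                         rtol=1e-12, atol=1e-12)
        assert tr.x1[i_post] == pytest.approx(sol2.y[0, -1], rel=1e-6)
        assert tr.x2[i_post] == pytest.approx(sol2.y[1, -1], rel=1e-6)

    def test_nonfinite_state_reported(self, fig2_params):
        # absurdly large step makes the integrator blow up in finite time
        noise = pl.NoiseSpec(0.0, 0.0, 1.0, 1.0)
        cfg = SimConfig(t_max=1000.0, dt=40.0, n_samples=1, burn_in=0, seed=0,
                        initial=pl.Point(4.0, 4.0))
        with pytest.raises(FloatingPointError, match="non-finite"):
            simulate.simulate_poisson(fig2_params, noise, cfg)

    def test_scheme_consistency(self, fig2_params, fig2_noise):
        edges = np.linspace(0.05, 4.0, 81)
        hists = {}
        for scheme in ("marcus_event", "dipaola_triangular"):
            cfg = SimConfig(scheme=scheme, t_max=2e4, dt=5e-3, n_samples=4,
                            burn_in=500.0, seed=11)
            trs = simulate.simulate_poisson(fig2_params, fig2_noise, cfg)
            hists[scheme] = simulate.pooled_marginal_histograms(trs, edges)
        w = edges[1] - edges[0]
        for i in range(2):
            L1 = np.sum(np.abs(hists["marcus_event"][i].values
                               - hists["dipaola_triangular"][i].values)) * w
            assert L1 < 0.08


class TestGaussian:
    def test_zero_intensity_is_deterministic(self, fig2_params):
        cfg = SimConfig(t_max=30.0, dt=1e-3, n_samples=1, burn_in=0, seed=0,
                        initial=pl.Point(1.5, 0.9))
        tr = simulate.simulate_gaussian(fig2_params, (0.0, 0.0), cfg)
        sol = solve_ivp(lambda t, z: pl.reduced_drift(z, fig2_params),
                        (0, 30.0), [1.5, 0.9], t_eval=tr.times,
                        rtol=1e-10, atol=1e-10)
        assert np.max(np.abs(sol.y[0] - tr.x1)) < 1e-5

    def test_log_increment_diffusion_scaling(self, fig2_params):
        D = (0.02, 0.01)
        cfg = SimConfig(t_max=5000.0, dt=5e-3, n_samples=1, burn_in=0, seed=21)
        tr = simulate.simulate_gaussian(fig2_params, D, cfg)
        dt_s = tr.times[1] - tr.times[0]
        for x, Di in ((tr.x1, D[0]), (tr.x2, D[1])):
            inc = np.diff(np.log(x))
            # drift contributes O(dt^2) to the increment variance
            assert inc.var() == pytest.approx(Di * dt_s, rel=0.1)

    def test_seeded_reproducibility(self, fig2_params):
        cfg = SimConfig(t_max=100.0, dt=5e-3, n_samples=2, burn_in=0, seed=4)
        a = simulate.simulate_gaussian(fig2_params, (0.015, 0.015), cfg)
        b = simulate.simulate_gaussian(fig2_params, (0.015, 0.015), cfg)
        np.testing.assert_array_equal(a[0].x1, b[0].x1)
        np.testing.assert_array_equal(a[1].x2, b[1].x2)


class TestDistributedDelay:
    def test_auxiliary_state_matches_convolution(self, fig2_params):
        cfg = SimConfig(t_max=40.0, dt=2e-3, n_samples=1, burn_in=0, seed=0,
                        initial=pl.Point(1.5, 0.9))
        tr = simulate.simulate_distributed_delay(fig2_params, None, cfg)
        z = tr.pulses.attrs["z"]
        g = fig2_params.eps2_gamma
        i = len(tr.times) - 100
        tau = tr.times[i] - tr.times[: i + 1]
        kern = np.exp(-tau / g) / g
        conv = np.trapezoid((kern * tr.x1[: i + 1])[::-1], tr.times[: i + 1])
        conv += np.exp(-tr.times[i] / g) * tr.x1[0]  # constant pre-history
        assert z[i] == pytest.approx(conv, rel=1e-2)

    def test_small_gamma_converges_to_classical(self):
        # as the mean delay shrinks, the chain system approaches the
        # classical Lotka-Volterra flow started from the same state
        base = dict(a=0.9, b=1.0, c=0.5, f=0.5, eps=0.1, s=0.0)
        cfg = SimConfig(t_max=25.0, dt=2e-3, n_samples=1, burn_in=0, seed=0,
                        initial=pl.Point(1.5, 0.9))
        classical = solve_ivp(
            lambda t, z: (z[0] * (0.9 - z[1]), z[1] * (-0.5 + 0.5 * z[0])),
            (0, 25.0), [1.5, 0.9], rtol=1e-10, atol=1e-10, dense_output=True)
        errs = []
        for g in (0.2, 0.05):
            p = pl.ModelParams(gamma=g / 0.01, **base)
            tr = simulate.simulate_distributed_delay(p, None, cfg)
            errs.append(np.max(np.abs(tr.x1 - classical.sol(tr.times)[0])))
        assert errs[1] < 0.5 * errs[0]

    def test_agrees_with_reduced_model_at_small_delay(self, fig2_params):
        cfg = SimConfig(t_max=60.0, dt=5e-3, n_samples=1, burn_in=0, seed=0,
                        initial=pl.Point(1.5, 0.9))
        tr = simulate.simulate_distributed_delay(fig2_params, None, cfg)
        sol = solve_ivp(lambda t, z: pl.reduced_drift(z, fig2_params),
                        (0, 60.0), [1.5, 0.9], t_eval=tr.times,
                        rtol=1e-10, atol=1e-10)
        # reduction error is O(gamma^2); a few percent at eps^2 gamma = 0.1
        rel = np.max(np.abs(sol.y[0] - tr.x1)) / np.max(tr.x1)
        assert rel < 0.05


class TestErgodicHistogram:
    def test_constant_trajectory_single_bin(self):
        tr = simulate.Trajectory(
            times=np.linspace(0, 10, 100), x1=np.full(100, 1.0),
            x2=np.full(100, 2.0), pulses=pd.DataFrame())
        edges = np.linspace(0, 4, 9)
        h = simulate.ergodic_histogram(tr, edges, burn_in=0.0)
        w = edges[1] - edges[0]
        assert np.sum(h.values) * w == pytest.approx(1.0, abs=1e-12)
        assert np.count_nonzero(h.values) == 1

    def test_empty_grid_raises(self):
        tr = simulate.Trajectory(
            times=np.linspace(0, 10, 100), x1=np.full(100, 10.0),
            x2=np.full(100, 10.0), pulses=pd.DataFrame())
        with pytest.raises(ValueError, match="empty"):
            simulate.ergodic_histogram(tr, np.linspace(0, 4, 9), burn_in=0.0)

    def test_pooling_reduces_monte_carlo_error(self, fig2_params, fig2_noise,
                                               fig2_pops):
        edges = np.linspace(0.05, 4.0, 81)
        w = edges[1] - edges[0]
        ana = fig2_pops.marg_x1(0.5 * (edges[:-1] + edges[1:]))

        def L1(n_samples):
            cfg = SimConfig(t_max=4000.0, dt=5e-3, n_samples=n_samples,
                            burn_in=500.0, seed=31)
            trs = simulate.simulate_poisson(fig2_params, fig2_noise, cfg)
            trs = trs if isinstance(trs, list) else [trs]
            h = simulate.ergodic_histogram(trs, edges, which="x1")
            return np.sum(np.abs(h.values - ana)) * w

        assert L1(8) < L1(1)
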