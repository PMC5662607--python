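import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import solve_ivp

from boutlangevin import (
    InvalidParameterError,
    ModelParams,
    MotionState,
    advance_within_bout,
    diffusive_asymptote,
    empirical_acc_autocov,
    ensemble_msd,
    ensemble_pdf,
    loglog_slope,
    msd_exact,
    positions_from_bouts,
    sample_displacements,
    simulate_positions,
)
from boutlangevin.simulator import _draw_bouts, _positions_kernel


class TestAdvanceWithinBout:
    def test_at_rest_without_forcing(self):
        s = MotionState(a_current=0.0, bout_end=10.0)
        s2 = advance_within_bout(s, 3.0, gamma=1.0)
        assert (s2.y, s2.v) == (0.0, 0.0)

    def test_terminal_velocity_balance(self):
        # a = gamma * v0: forcing balances drag, v stays at v0 = a/gamma
        s = MotionState(v=2.0, a_current=1.0, bout_end=100.0)
        s2 = advance_within_bout(s, 57.0, gamma=0.5)
        assert s2.v == pytest.approx(2.0, rel=1e-12)
        assert s2.y == pytest.approx(2.0 * 57.0, rel=1e-12)

    def test_closed_form_values(self):
        s = MotionState(a_current=1.0, bout_end=2.0)
        s2 = advance_within_bout(s, 1.0, gamma=1.0)
        assert s2.v == pytest.approx(1 - math.exp(-1), rel=1e-14)
        assert s2.y == pytest.approx(math.exp(-1), rel=1e-14)

    def test_against_ode_integrator(self):
        # independent oracle: integrate dv/dt = -gamma v + a numerically
        gamma, a, v0, dt = 0.7, 1.3, 0.4, 1.9
        sol = solve_ivp(
            lambda t, s: [s[1], -gamma * s[1] + a],
            (0, dt),
            [0.0, v0],
            rtol=1e-12,
            atol=1e-14,
        )
        s2 = advance_within_bout(
            MotionState(v=v0, a_current=a, bout_end=10.0), dt, gamma
        )
        assert s2.y == pytest.approx(sol.y[0, -1], rel=1e-9)
        assert s2.v == pytest.approx(sol.y[1, -1], rel=1e-9)

    @settings(derandomize=True, max_examples=60)
    @given(
        gamma=st.floats(0.0, 50.0),
        a=st.floats(-5.0, 5.0),
        v0=st.floats(-5.0, 5.0),
        dt=st.floats(1e-6, 5.0),
        split=st.floats(0.05, 0.95),
    )
    def test_additivity(self, gamma, a, v0, dt, split):
        s0 = MotionState(v=v0, a_current=a, bout_end=100.0)
        once = advance_within_bout(s0, dt, gamma)
        mid = advance_within_bout(s0, dt * split, gamma)
        twice = advance_within_bout(mid, dt * (1 - split), gamma)
        assert twice.y == pytest.approx(once.y, rel=1e-12, abs=1e-12)
        assert twice.v == pytest.approx(once.v, rel=1e-12, abs=1e-12)

    def test_contract_violations(self):
        s = MotionState(a_current=1.0, bout_end=1.0)
        with pytest.raises(InvalidParameterError):
            advance_within_bout(s, 2.0, gamma=1.0)
        with pytest.raises(InvalidParameterError):
            advance_within_bout(s, -0.1, gamma=1.0)


class TestPositionsFromBouts:
    def test_zero_forcing_stays_at_rest(self):
        x = positions_from_bouts([0.0, 0.0], [1.0, 5.0], 1.0, [0.5, 3.0])
        assert np.all(x == 0.0)

    def test_empty_bout_list(self):
        assert positions_from_bouts([], [], 1.0, [0.0, 1.0]).tolist() == [0.0, 0.0]

    def test_single_bout_closed_form(self):
        # one long bout: position is the within-bout solution directly
        times = np.array([0.3, 1.0, 2.5])
        x = positions_from_bouts([1.0], [10.0], 1.0, times)
        expected = times + np.exp(-times) - 1.0
        assert np.allclose(x, expected, rtol=1e-12)

    def test_matches_stateful_recurrence(self, rng):
        # independent path: walk the bouts with advance_within_bout,
        # truncating the active bout at each observation time
        gamma = 0.8
        durations = rng.standard_exponential(20)
        accels = rng.standard_normal(20)
        sample_times = np.sort(rng.uniform(0, durations.sum(), 7))
        expected = []
        for s in sample_times:
            state = MotionState(a_current=accels[0], bout_end=durations[0])
            elapsed = 0.0
            for a, d in zip(accels, durations):
                state = MotionState(
                    t=state.t,
                    y=state.y,
                    v=state.v,
                    bout_index=state.bout_index,
                    a_current=a,
                    bout_end=elapsed + d,
                )
                step = min(d, s - elapsed)
                state = advance_within_bout(state, step, gamma)
                elapsed += d
                if elapsed >= s:
                    break
            expected.append(state.y)
        x = positions_from_bouts(accels, durations, gamma, sample_times)
        assert np.allclose(x, expected, rtol=1e-10, atol=1e-12)

    def test_kernel_matches_row_oracle(self, rng):
        # the vectorised ensemble kernel equals the per-trajectory evaluation
        dur = rng.standard_exponential((6, 50))
        acc = rng.standard_normal((6, 50))
        ends = np.cumsum(dur, axis=1)
        st_ = np.array([0.0, 1.0, 7.0, 30.0])
        for gamma in (0.0, 1e-3, 1.0, 20.0):
            X = _positions_kernel(acc, dur, ends, gamma, st_)
            for i in range(6):
                ref = positions_from_bouts(acc[i], dur[i], gamma, st_)
                assert np.allclose(X[i], ref, rtol=1e-10, atol=1e-13), gamma


class TestSimulatePositions:
    def test_deterministic(self, unit_params):
        t = np.linspace(0.0, 20.0, 9)
        x1 = simulate_positions(unit_params, t, seed=42)
        x2 = simulate_positions(unit_params, t, seed=42)
        assert np.array_equal(x1, x2)
        x3 = simulate_positions(unit_params, t, seed=43)
        assert not np.array_equal(x1, x3)

    def test_empty_sample_times(self, unit_params):
        assert simulate_positions(unit_params, [], seed=1).size == 0

    def test_starts_at_origin(self, unit_params):
        x = simulate_positions(unit_params, [0.0, 1.0], seed=7)
        assert x[0] == 0.0


class TestEnsembleMsd:
    def test_degenerate_ensemble(self, unit_params):
        est = ensemble_msd(unit_params, [1.0, 2.0], n=2, seed=0)
        assert np.all(np.isfinite(est.se))
        assert np.all(est.msd_hat >= 0)

    def test_matches_exact_theory(self, unit_params):
        tau = np.geomspace(1e-2, 1e2, 12)
        est = ensemble_msd(unit_params, tau, n=20_000, seed=1)
        exact = msd_exact(1.0, tau)
        within = np.abs(est.msd_hat - exact) <= 4.0 * est.se
        assert within.mean() >= 0.95

    def test_family_invariance(self):
        # gaussian and uniform forcing with equal variance: same MSD
        tau = np.geomspace(0.1, 30.0, 8)
        ests = []
        for fam in ("gaussian", "uniform"):
            p = ModelParams(nu_a2=1.0, omega=1.0, gamma=1.0, accel_dist=fam)
            ests.append(ensemble_msd(p, tau, n=20_000, seed=5))
        diff = np.abs(ests[0].msd_hat - ests[1].msd_hat)
        band = 4.0 * np.hypot(ests[0].se, ests[1].se)
        assert np.all(diff <= band)

    def test_two_dimensional_consistency(self, unit_params):
        # two independent coordinates: <r^2> = 2 <x^2>
        tau = np.array([1.0, 10.0])
        ex = ensemble_msd(unit_params, tau, n=20_000, seed=10)
        ey = ensemble_msd(unit_params, tau, n=20_000, seed=11)
        r2 = ex.msd_hat + ey.msd_hat
        band = 4.0 * np.hypot(ex.se, ey.se)
        assert np.all(np.abs(r2 - 2 * msd_exact(1.0, tau)) <= band)

    def test_superballistic_onset_slope(self, unit_params):
        tau0 = 1e-2
        tau = np.array([tau0 * 0.8, tau0 * 1.25])
        est = ensemble_msd(unit_params, tau, n=20_000, seed=3)
        slope = math.log(est.msd_hat[1] / est.msd_hat[0]) / math.log(
            tau[1] / tau[0]
        )
        assert slope == pytest.approx(4.0, abs=0.15)

    def test_diffusive_tail_recovers_diffusion_coefficient(self):
        # late-time MSD/(2 t) estimates D = nu_a2/(gamma^2 omega)
        p = ModelParams(nu_a2=1.0, omega=1.0, gamma=2.0)
        t_late = 1e3
        tau = np.array([t_late * 0.7, t_late])
        est = ensemble_msd(p, tau, n=50_000, seed=8)
        slope = math.log(est.msd_hat[1] / est.msd_hat[0]) / math.log(
            tau[1] / tau[0]
        )
        assert slope == pytest.approx(1.0, abs=0.1)
        d_hat = est.msd_hat[1] / (2 * t_late)
        assert d_hat == pytest.approx(0.25, rel=0.05)


class TestEnsemblePdf:
    def test_symmetry_and_renormalisation(self, unit_params):
        est = ensemble_pdf(unit_params, tau=8.0, n=50_000, n_bins=81, seed=2)
        skew = stats.skew(est.samples)
        se_skew = math.sqrt(6.0 / len(est.samples))
        assert abs(skew) < 5 * se_skew
        centre = len(est.bin_centers) // 2
        assert est.bin_centers[centre] == pytest.approx(0.0, abs=1e-12)
        assert est.density_renorm[centre] == 1.0
        width = est.bin_centers[1] - est.bin_centers[0]
        assert est.density.sum() * width == pytest.approx(1.0, abs=1e-2)

    def test_early_time_exponential_tail_kurtosis(self, unit_params):
        # at tau ~ 1 the kernel is leptokurtic (fatter than Gaussian)
        est = ensemble_pdf(unit_params, tau=1.0, n=100_000, n_bins=81, seed=6)
        kurt = stats.kurtosis(est.samples)
        se_kurt = math.sqrt(24.0 / len(est.samples))
        assert kurt > 5 * se_kurt

    def test_large_time_gaussianity(self, unit_params):
        est = ensemble_pdf(unit_params, tau=256.0, n=50_000, n_bins=81, seed=9)
        sd = math.sqrt(diffusive_asymptote(1.0, 256.0))
        ks = stats.kstest(est.samples, "norm", args=(0.0, sd)).statistic
        assert ks < 0.02

    def test_starved_central_bin_warns(self, unit_params):
        with pytest.warns(RuntimeWarning, match="central bin"):
            ensemble_pdf(unit_params, tau=64.0, n=1000, n_bins=99_991, seed=1)

    def test_minimum_sample_size_enforced(self, unit_params):
        with pytest.raises(InvalidParameterError):
            ensemble_pdf(unit_params, tau=1.0, n=10, n_bins=11, seed=0)


class TestForcingAutocovariance:
    def test_exponential_decay_recovered(self, unit_params):
        lags = np.array([0.0, 1.0, 20.0])
        _, est, se = empirical_acc_autocov(
            unit_params, lags, total_time=1e5, seed=13
        )
        expected = np.exp(-lags)
        assert np.all(np.abs(est - expected) <= 5 * se)

    def test_too_short_realisation_rejected(self, unit_params):
        with pytest.raises(InvalidParameterError):
            empirical_acc_autocov(unit_params, [1.0], total_time=10.0, seed=0)


class TestCoverage:
    def test_draw_bouts_covers_horizon(self, unit_params, rng):
        dur, acc, ends = _draw_bouts(unit_params, 50, 30.0, rng)
        assert np.all(ends[:, -1] > 30.0)
        assert dur.shape == acc.shape == ends.shape

    def test_sample_displacements_distribution_scale(self, unit_params):
        x = sample_displacements(unit_params, 100.0, 5000, seed=4)
        # variance should be near the exact MSD at tau = 100
        target = msd_exact(1.0, 100.0)
        se = target * math.sqrt(2.0 / 5000)
        assert abs(x.var() - target) < 5 * se
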