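"""Stochastic Adler equation: simulation, bifurcation, inference, scaling."""

import math

import numpy as np
import pytest

from flagsync import adler, phase, synthetic


def drift_rate_oracle(params, duration=300.0, dt=1e-4):
    """Mean winding rate by first/last integer-crossing (no partial-cycle bias)."""
    t, d = adler.simulate_adler(params, delta0=0.0, dt=dt, duration=duration,
                                seed=0, sample_every=10)
    wind = np.floor(d)
    changes = np.nonzero(np.diff(wind))[0]
    if len(changes) < 3:
        return 0.0
    t_first, t_last = t[changes[0]], t[changes[-1]]
    return (wind[changes[-1] + 1] - wind[changes[0] + 1]) / (t_last - t_first)


class TestSimulate:
    def test_pure_drift_exact(self):
        p = adler.AdlerParams(eps=0.0, delta_nu=1.0, T_eff=0.0)
        t, d = adler.simulate_adler(p, delta0=0.3, dt=1e-4, duration=2.0, seed=0)
        np.testing.assert_allclose(d, 0.3 + t, rtol=1e-9)

    def test_relaxation_to_fixed_point(self):
        p = adler.AdlerParams(eps=0.5, delta_nu=0.0, T_eff=0.0)
        _, d = adler.simulate_adler(p, delta0=0.2, dt=1e-4, duration=5.0, seed=0)
        assert np.all(np.diff(d) <= 1e-15)
        assert abs(d[-1]) < 1e-8

    def test_detuned_fixed_point_is_arcsin(self):
        p = adler.AdlerParams(eps=0.5, delta_nu=1.0, T_eff=0.0)
        _, d = adler.simulate_adler(p, delta0=0.0, dt=1e-4, duration=10.0, seed=0)
        assert d[-1] == pytest.approx(adler.locked_fixed_point(p), abs=1e-8)
        assert adler.locked_fixed_point(p) == pytest.approx(
            math.asin(1.0 / (2 * math.pi * 0.5)) / (2 * math.pi))

    def test_ou_variance_identity_in_harmonic_regime(self):
        # symmetric well (delta_nu = 0): Var(Delta) = T_eff/(4 pi^2 eps)
        p = adler.AdlerParams(eps=0.528, delta_nu=0.0, T_eff=0.033)
        _, d = adler.simulate_adler(p, delta0=0.0, dt=1e-4, duration=100.0,
                                    seed=11)
        well = d[np.round(d) == 0]
        pred = p.T_eff / (4 * math.pi**2 * p.eps)
        assert abs(well.var() / pred - 1) < 0.1

    def test_unstable_dt_rejected(self):
        p = adler.AdlerParams(eps=50.0, delta_nu=0.0, T_eff=0.0)
        with pytest.raises(ValueError):
            adler.simulate_adler(p, dt=1e-2, duration=1.0)

    def test_seeded_reproducibility(self):
        p = adler.AdlerParams(eps=0.5, delta_nu=1.0, T_eff=0.1)
        _, d1 = adler.simulate_adler(p, dt=1e-4, duration=1.0, seed=42)
        _, d2 = adler.simulate_adler(p, dt=1e-4, duration=1.0, seed=42)
        np.testing.assert_array_equal(d1, d2)

    def test_detuning_sign_symmetry(self):
        # (delta_nu, Delta) -> (-delta_nu, -Delta) leaves the dynamics invariant
        pp = adler.AdlerParams(eps=0.4, delta_nu=1.2, T_eff=0.0)
        pm = adler.AdlerParams(eps=0.4, delta_nu=-1.2, T_eff=0.0)
        _, dp = adler.simulate_adler(pp, delta0=0.05, dt=1e-4, duration=5.0, seed=0)
        _, dm = adler.simulate_adler(pm, delta0=-0.05, dt=1e-4, duration=5.0, seed=0)
        np.testing.assert_allclose(dp, -dm, atol=1e-12)


class TestBifurcation:
    @pytest.mark.parametrize("x,expected", [
        (0.0, 1.0),
        (1.0, 0.0),
        (0.5, math.sqrt(3) / 2),
    ])
    def test_noise_free_prediction_values(self, x, expected):
        delta_nu = 1.9
        assert adler.predicted_freq_diff(x * delta_nu / (2 * math.pi), delta_nu) \
            == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("x", [0.0, 0.5, 0.9])
    def test_prediction_matches_deterministic_simulation(self, x):
        delta_nu = 1.9
        eps = x * delta_nu / (2 * math.pi)
        p = adler.AdlerParams(eps=eps, delta_nu=delta_nu, T_eff=0.0)
        measured = drift_rate_oracle(p) / delta_nu
        assert measured == pytest.approx(adler.predicted_freq_diff(eps, delta_nu),
                                         abs=0.01)

    def test_noisy_reduces_to_deterministic_without_noise(self):
        delta_nu = 1.9
        eps = 0.5 * delta_nu / (2 * math.pi)
        p = adler.AdlerParams(eps=eps, delta_nu=delta_nu, T_eff=0.0)
        mean, _ = adler.noisy_freq_diff(p, duration=100.0, seeds=[0])
        assert mean == pytest.approx(adler.predicted_freq_diff(eps, delta_nu),
                                     abs=0.02)

    def test_noise_rounds_the_bifurcation(self):
        # exactly at the deterministic bifurcation the noisy ratio is > 0
        delta_nu = 1.9
        eps = delta_nu / (2 * math.pi)
        p = adler.AdlerParams(eps=eps, delta_nu=delta_nu, T_eff=0.165)
        mean, sem = adler.noisy_freq_diff(p, duration=50.0, seeds=range(20))
        assert mean > 3 * sem > 0

    def test_monotone_in_noise_strength(self):
        delta_nu = 1.9
        eps = 1.1 * delta_nu / (2 * math.pi)  # just inside the locked regime
        means = []
        for teff in (0.05, 0.15, 0.45):
            p = adler.AdlerParams(eps=eps, delta_nu=delta_nu, T_eff=teff)
            m, _ = adler.noisy_freq_diff(p, duration=50.0, seeds=range(10))
            means.append(m)
        assert means[0] < means[1] < means[2]


class TestAutocorrelation:
    def _ou(self, r, D, n, dt, seed):
        rng = np.random.default_rng(seed)
        x = np.empty(n)
        x[0] = 0.0
        g = math.sqrt(2 * D * dt) * rng.standard_normal(n)
        for i in range(1, n):
            x[i] = x[i - 1] * (1 - r * dt) + g[i]
        return x

    def test_ou_parameters_recovered(self):
        r, D, dt = 20.0, 0.165, 1e-3
        x = self._ou(r, D, 10**5, dt, seed=1)
        ac = adler.autocorrelation(x, dt, max_lag=0.5)
        assert ac["ok"]
        assert ac["C0"] == pytest.approx(D / r, rel=0.1)
        assert ac["tau_r"] == pytest.approx(1 / r, rel=0.1)

    def test_c0_equals_sample_variance_when_stationary(self):
        x = self._ou(20.0, 0.165, 10**5, 1e-3, seed=2)
        ac = adler.autocorrelation(x, 1e-3, max_lag=0.5)
        assert ac["C0"] == pytest.approx(x.var(), rel=0.05)

    def test_white_noise_flagged(self):
        rng = np.random.default_rng(0)
        ac = adler.autocorrelation(rng.standard_normal(5000), 1e-3)
        assert not ac["ok"] or ac["tau_r"] < 5e-3


class TestInference:
    def test_recovery_at_population_mean_parameters(self):
        params = synthetic.adler_params_at_separation(0.016, L=0.85)
        errs = []
        for seed in range(8):
            cfg = synthetic.SyntheticConfig(seed=seed, duration=100.0)
            pair = synthetic.generate_pair_phases(cfg, params, L=0.85)
            est = adler.infer_params(pair)
            errs.append([abs(est.eps / params.eps - 1),
                         abs(est.delta_nu / params.delta_nu - 1),
                         abs(est.T_eff / params.T_eff - 1)])
        assert np.all(np.median(np.array(errs), axis=0) < 0.2)

    def test_noiseless_locked_series_gives_zero_temperature(self):
        params = synthetic.adler_params_at_separation(
            0.016, L=1.0, delta_nu_ratio=0.02, teff_ratio=0.0)
        cfg = synthetic.SyntheticConfig(seed=0, duration=40.0)
        pair = synthetic.generate_pair_phases(cfg, params, L=1.0)
        est = adler.infer_params(pair)
        assert est.T_eff < 1e-3 * params.omega_bar

    def test_antiphase_series_yields_negative_coupling(self):
        params = synthetic.adler_params_at_separation(
            0.016, L=1.0, delta_nu_ratio=0.02, teff_ratio=0.003,
            orientation="AP")
        assert params.eps < 0
        cfg = synthetic.SyntheticConfig(seed=1, duration=60.0)
        pair = synthetic.generate_pair_phases(cfg, params, L=1.0, delta0=0.5)
        est = adler.infer_params(pair)
        assert est.eps < 0
        assert abs(est.eps / params.eps - 1) < 0.3

    def test_never_locked_series_returns_drift_only(self):
        params = synthetic.adler_params_at_separation(
            0.0, L=1.0, delta_nu_ratio=0.058, teff_ratio=0.001)
        cfg = synthetic.SyntheticConfig(seed=0, duration=30.0)
        pair = synthetic.generate_pair_phases(cfg, params, L=1.0)
        est = adler.infer_params(pair)
        assert est.eps == 0.0
        assert est.delta_nu == pytest.approx(params.delta_nu, rel=0.05)


class TestSlipStatistics:
    def test_slip_rate_monotone_in_noise_and_coupling(self):
        # 2x2 corner of the parameter grid: more noise -> more slips,
        # stronger coupling -> fewer slips
        def slip_rate(eps, teff):
            p = adler.AdlerParams(eps=eps, delta_nu=0.5, T_eff=teff)
            total = 0
            for seed in range(4):
                _, d = adler.simulate_adler(p, dt=2e-4, duration=60.0,
                                            seed=seed, sample_every=10)
                total += abs(int(round(d[-1]) - round(d[0])))
            return total
        base = slip_rate(0.3, 0.1)
        assert slip_rate(0.3, 0.25) > base
        assert slip_rate(0.6, 0.1) < base


class TestCouplingLaw:
    L_GRID = np.array([0.85, 1.22, 1.69, 2.27])

    def test_exact_inverse_law_recovered(self):
        kappa = 0.016 / self.L_GRID
        fit = adler.fit_coupling_law(self.L_GRID, kappa)
        assert fit.k == pytest.approx(0.016, rel=1e-12)
        assert fit.loglog_slope == pytest.approx(-1.0, abs=1e-9)

    def test_noisy_fit_accuracy(self):
        rng_master = np.random.default_rng(0)
        ks = []
        for _ in range(100):
            L = np.linspace(0.8, 2.5, 8)
            kappa = 0.016 / L * rng_master.lognormal(0, 0.1, 8)
            ks.append(adler.fit_coupling_law(L, kappa).k)
        assert abs(np.median(ks) / 0.016 - 1) < 0.1

    def test_linearity_in_kappa(self):
        kappa = 0.016 / self.L_GRID
        k1 = adler.fit_coupling_law(self.L_GRID, kappa).k
        k2 = adler.fit_coupling_law(self.L_GRID, 2 * kappa).k
        assert k2 == pytest.approx(2 * k1)

    def test_degenerate_points_rejected(self):
        with pytest.raises(ValueError):
            adler.fit_coupling_law(np.array([1.0, 1.0, 1.0]),
                                   np.array([1.0, 2.0, 3.0]))


class TestTeffFromPeriods:
    def _periods(self, f0, D1, n_beats, seed):
        rng = np.random.default_rng(seed)
        dt = 1e-4
        n = int(1.2 * n_beats / f0 / dt)
        phi = np.cumsum(f0 * dt + math.sqrt(2 * D1 * dt) * rng.standard_normal(n))
        run = np.maximum.accumulate(phi)
        t = np.arange(n) * dt
        crossings = np.interp(np.arange(1, int(run[-1])), run, t)
        return np.diff(crossings)

    def test_first_passage_oracle_recovery(self):
        D1 = 0.08
        est = adler.teff_from_periods(self._periods(33.0, D1, 1000, seed=0))
        assert est == pytest.approx(D1, rel=0.15)

    def test_zero_noise_gives_zero(self):
        periods = np.full(500, 1 / 33.0)
        assert adler.teff_from_periods(periods) == pytest.approx(0.0, abs=1e-15)

    def test_linear_in_period_variance(self):
        rng = np.random.default_rng(3)
        base = 1 / 33 + rng.normal(0, 1e-3, 1000)
        wide = 1 / 33 + 2 * (base - 1 / 33)  # variance x4
        est_b = adler.teff_from_periods(base)
        est_w = adler.teff_from_periods(wide)
        assert est_w / est_b == pytest.approx(4.0, rel=0.02)

    def test_too_few_periods_rejected(self):
        with pytest.raises(ValueError):
            adler.teff_from_periods(np.full(50, 0.03))


class TestEndToEnd:
    def test_full_loop_recovers_coupling_law(self):
        # generator -> phase statistics -> inference -> 1/L fit
        Ls = [0.85, 1.22, 1.69, 2.27]
        kappas = []
        for i, L in enumerate(Ls):
            params = synthetic.adler_params_at_separation(
                0.016, L=L, delta_nu_ratio=0.005, teff_ratio=0.001)
            cfg = synthetic.SyntheticConfig(seed=60 + i, duration=60.0)
            pair = synthetic.generate_pair_phases(cfg, params, L=L)
            kappas.append(adler.infer_params(pair).kappa)
        fit = adler.fit_coupling_law(np.array(Ls), np.array(kappas))
        assert abs(fit.k / 0.016 - 1) < 0.1
        assert abs(fit.loglog_slope + 1.0) < 0.1
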