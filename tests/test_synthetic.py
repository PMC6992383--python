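"""Synthetic-data generator: distributional structure and determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from flaglen.datatypes import (
    ConfigurationError,
    FlagellarGeometry,
    FrapModelParams,
    ParameterError,
    TrainEvent,
)
from flaglen.scenarios import PairStats, get_scenario, list_scenarios
from flaglen.synthetic import (
    frap_mean_curve,
    generate_flagellar_geometry,
    render_kymograph,
    simulate_auc_vs_length,
    simulate_frap_trace,
    simulate_injection_process,
    simulate_tip_profile,
)


class TestGeometry:
    def test_anterior_membrane_mean_matches_published_value(self, wbc6):
        """n=10⁴ anterior draws: sample mean within 2 SE of 12.8 µm."""
        table = generate_flagellar_geometry(wbc6, 10_000, seed=7)
        ant = table[table.pair == "anterior"]["membrane_length"]
        se = wbc6.pair_stats("anterior").membrane_sd / np.sqrt(len(ant))
        assert abs(ant.mean() - 12.8) < 2 * se

    def test_zero_sd_is_degenerate_at_the_mean(self, wbc6):
        pairs = {
            k: dataclasses.replace(v, membrane_sd=0.0, cytoplasmic_sd=0.0)
            for k, v in wbc6.pairs.items()
        }
        cfg = dataclasses.replace(wbc6, pairs=pairs)
        table = generate_flagellar_geometry(cfg, 50, seed=0)
        for pair, grp in table.groupby("pair"):
            assert np.all(grp.membrane_length == cfg.membrane_mean(pair))
            assert np.all(
                grp.cytoplasmic_length == cfg.pair_stats(pair).cytoplasmic_mean
            )

    def test_sample_sd_within_bootstrap_ci_of_configured_sd(self, wbc6):
        """Oracle: Monte-Carlo resampling of the stated truncated-normal model."""
        n = 500
        table = generate_flagellar_geometry(wbc6, n, seed=11)
        obs_sd = table[table.pair == "anterior"]["membrane_length"].std(ddof=1)
        ps = wbc6.pair_stats("anterior")
        rng = np.random.default_rng(123)
        a = -ps.membrane_mean / ps.membrane_sd
        boot = [
            stats.truncnorm.rvs(a, np.inf, loc=ps.membrane_mean,
                                scale=ps.membrane_sd, size=n,
                                random_state=rng).std(ddof=1)
            for _ in range(500)
        ]
        lo, hi = np.percentile(boot, [2.5, 97.5])
        assert lo < obs_sd < hi

    def test_deterministic_under_fixed_seed(self, wbc6):
        t1 = generate_flagellar_geometry(wbc6, 200, seed=3)
        t2 = generate_flagellar_geometry(wbc6, 200, seed=3)
        assert t1.equals(t2)

    def test_missing_pair_parameters_raise(self, wbc6):
        cfg = dataclasses.replace(
            wbc6, pairs={"anterior": wbc6.pair_stats("anterior")}
        )
        with pytest.raises(ConfigurationError):
            cfg.pair_stats("caudal")

    def test_n_cells_must_be_positive(self, wbc6):
        with pytest.raises(ParameterError):
            generate_flagellar_geometry(wbc6, 0, seed=1)


class TestInjectionProcess:
    def test_zero_duration_gives_no_events(self):
        assert simulate_injection_process(1.0, 0.0, seed=1) == []

    def test_sample_mean_interval_within_two_percent(self, wbc6):
        """10⁴ intervals at the anterior mean (1.0 s) recover it to 2%."""
        tau = wbc6.pair_stats("anterior").injection_mean_interval
        events = simulate_injection_process(tau, 1.05e4 * tau, seed=1)
        times = np.array([e.injection_time for e in events])
        intervals = np.diff(times)[:10_000]
        assert intervals.size == 10_000
        assert abs(intervals.mean() - tau) / tau < 0.02

    def test_intervals_pass_ks_against_exponential_cdf(self):
        """KS distance below the α=0.01 critical value in ≥98/100 seeds."""
        tau, n = 1.2, 10_000
        crit = stats.ksone.ppf(1 - 0.005, n)  # two-sided α=0.01
        passed = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            iv = rng.exponential(tau, n)
            d = stats.kstest(iv, "expon", args=(0, tau)).statistic
            passed += d < crit
        assert passed >= 98
        # the generator draws from the same law: spot-check a few seeds
        for seed in (0, 1, 2):
            ev = simulate_injection_process(tau, 2_000 * tau, seed=seed)
            iv = np.diff([e.injection_time for e in ev])
            assert stats.kstest(iv, "expon", args=(0, tau)).pvalue > 1e-4

    def test_event_count_mean_matches_duration_over_tau(self):
        """Poisson process: E[count over T] = T/τ, within 3 SE over 200 reps."""
        tau, T, reps = 1.3, 50.0, 200
        counts = [
            len(simulate_injection_process(tau, T, seed=s)) for s in range(reps)
        ]
        expected = T / tau
        se = np.sqrt(expected / reps)  # var of Poisson mean-count estimate
        assert abs(np.mean(counts) - expected) < 3 * se

    def test_events_sorted_and_positive_speed(self):
        ev = simulate_injection_process(0.5, 30, seed=2, speed=3.2)
        times = [e.injection_time for e in ev]
        assert times == sorted(times)
        assert all(e.speed > 0 for e in ev)

    def test_nonpositive_mean_interval_rejected(self):
        with pytest.raises(ParameterError):
            simulate_injection_process(0.0, 10.0, seed=1)


class TestKymographRendering:
    def test_empty_scene_is_constant_background(self, anterior_geometry):
        k = render_kymograph([], anterior_geometry, noise_sd=0.0)
        assert np.all(k.grid == 0.0)

    def test_argmax_positions_regress_to_ground_truth_speed(
        self, anterior_geometry
    ):
        """Oracle: linear regression on the known analytic trajectory."""
        v = 3.1
        ev = [TrainEvent(injection_time=0.5, speed=v, intensity=100.0)]
        k = render_kymograph(ev, anterior_geometry, pixel_size=0.1,
                             frame_interval=1 / 13)
        rows = np.nonzero(k.grid.max(axis=1) > 10)[0]
        rows = rows[2:-2]  # clip entry/exit frames where the spot is cut
        pos = k.grid[rows].argmax(axis=1) * k.pixel_size
        slope = stats.linregress(rows * k.frame_interval, pos).slope
        # pixel/frame quantization bound on the argmax estimate
        assert abs(slope - v) < k.pixel_size / k.frame_interval

    def test_default_acquisition_spans_about_26_seconds(self, anterior_geometry):
        k = render_kymograph([], anterior_geometry)
        assert k.n_frames == 330
        assert 25.0 < k.duration < 26.5

    def test_photon_budget_conserved_mid_field(self, anterior_geometry):
        """Noise- and bleach-free train: per-frame total intensity constant
        while fully inside the field."""
        ev = [TrainEvent(injection_time=0.0, speed=3.1, intensity=50.0)]
        k = render_kymograph(ev, anterior_geometry, n_frames=50)
        sums = k.grid.sum(axis=1)
        inside = sums > 0.5 * sums.max()
        mid = sums[inside][3:-3]
        assert mid.std() / mid.mean() < 1e-6

    def test_undersampled_train_warns(self, anterior_geometry):
        ev = [TrainEvent(injection_time=0.0, speed=500.0, intensity=10.0)]
        with pytest.warns(RuntimeWarning, match="under-sampled"):
            render_kymograph(ev, anterior_geometry)

    def test_deterministic_under_fixed_seed(self, anterior_geometry):
        ev = [TrainEvent(injection_time=1.0, speed=3.1, intensity=80.0)]
        k1 = render_kymograph(ev, anterior_geometry, noise_sd=5.0, seed=42)
        k2 = render_kymograph(ev, anterior_geometry, noise_sd=5.0, seed=42)
        assert np.array_equal(k1.grid, k2.grid)


class TestFrapTraceSimulation:
    def test_frozen_pool_never_recovers(self):
        p = FrapModelParams(D=0.0, I0=1.0, omega=2.0)
        tr = simulate_frap_trace("cytoplasmic", p, 100, 1.0)
        assert np.all(tr.intensity == 0.0)

    def test_noise_free_trace_equals_closed_form(self, cyto_frap_params):
        """Oracle: direct evaluation of I0·(1 − ω/√(ω²+4πDt))."""
        p = cyto_frap_params
        tr = simulate_frap_trace("cytoplasmic", p, 300, 1.0)
        expected = p.I0 * (
            1 - p.omega / np.sqrt(p.omega**2 + 4 * np.pi * p.D * tr.time)
        )
        np.testing.assert_allclose(tr.intensity, expected, atol=1e-12)

    def test_short_time_limit_is_the_linear_law(self, cyto_frap_params):
        """For t < 0.01·ω²/(4πD) the strip law is within 1% of I0·2πDt/ω²."""
        p = cyto_frap_params
        t_lim = 0.01 * p.omega**2 / (4 * np.pi * p.D)
        t = np.linspace(t_lim / 50, t_lim, 40)
        exact = frap_mean_curve("cytoplasmic", p, t)
        linear = p.I0 * 2 * np.pi * p.D * t / p.omega**2
        np.testing.assert_allclose(exact, linear, rtol=0.01)

    def test_tip_trace_plateaus_at_mobile_fraction(self, tip_frap_params):
        tr = simulate_frap_trace("tip", tip_frap_params, 5000, 5.0)
        plateau = tip_frap_params.f_mobile * tip_frap_params.I0
        assert tr.intensity[-1] == pytest.approx(plateau, rel=0.05)
        assert tr.intensity.max() <= plateau + 1e-12

    def test_negative_parameters_rejected(self):
        with pytest.raises(ParameterError):
            FrapModelParams(D=-0.01)
        with pytest.raises(ParameterError):
            FrapModelParams(D=0.01, omega=-1.0)


class TestTipProfileSimulation:
    def test_large_lambda_limit_is_flat(self):
        prof = simulate_tip_profile(lambda_=1.2e3, I0=2.0, window=1.2)
        np.testing.assert_allclose(prof.intensity, 2.0, rtol=1e-3)

    def test_tip_to_window_ratio_is_cosh_of_window_over_lambda(self):
        """λ=0.3, window=1.2 → I(0)/I(1.2) = cosh(4) ≈ 27.31."""
        prof = simulate_tip_profile(lambda_=0.3, I0=1.0, window=1.2)
        assert prof.intensity[0] / prof.intensity[-1] == pytest.approx(
            np.cosh(4.0), rel=1e-12
        )

    def test_profile_strictly_decreasing_from_tip(self):
        prof = simulate_tip_profile(lambda_=0.25, I0=1.0, window=1.2)
        assert np.all(np.diff(prof.intensity) < 0)


class TestScenarios:
    def test_packaged_scenarios_present(self):
        for name in ("wbc6", "wbc6-tip", "taxol-1h", "taxol-5h", "k13kd"):
            assert name in list_scenarios()

    def test_taxol_and_knockdown_shift_membrane_means(self):
        wbc6 = get_scenario("wbc6")
        taxol = get_scenario("taxol-1h")
        k13 = get_scenario("k13kd")
        assert taxol.membrane_mean("caudal") == pytest.approx(
            wbc6.membrane_mean("caudal") * 1.61
        )
        assert k13.membrane_mean("caudal") == pytest.approx(
            wbc6.membrane_mean("caudal") + 3.1
        )

    def test_pair_sd_backcomputed_from_ci(self, wbc6):
        # 95% CI halfwidth 0.1 µm, n=35 → sd = 0.1·√35/1.96
        assert wbc6.pair_stats("anterior").membrane_sd == pytest.approx(
            0.1 * np.sqrt(35) / 1.96
        )

    def test_invalid_pair_stats_rejected(self):
        with pytest.raises(ParameterError):
            PairStats(membrane_mean=-1, membrane_sd=0.1,
                      cytoplasmic_mean=5, cytoplasmic_sd=0.1,
                      injection_mean_interval=1.0)


class TestAucGenerator:
    def test_population_r2_calibration(self, wbc6):
        """Pooled AUC-vs-length sample R² close to the 0.89 target."""
        r2s = []
        for seed in range(30):
            df = simulate_auc_vs_length(wbc6, 60, seed=seed)
            x, y = df["length"], df["auc"]
            r2s.append(stats.pearsonr(x, y).statistic ** 2)
        assert abs(np.mean(r2s) - wbc6.auc_r2_target) < 0.05
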