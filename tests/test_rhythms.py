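"""Chi-squared periodogram, detrending, damped-cosine fitting."""

import numpy as np
import pytest

from chronosim.dynamics import Trajectory
from chronosim.rhythms import (
    chi_squared_periodogram,
    circular_phase_diff,
    detrend,
    estimate_free_running_period,
    find_peaks_interp,
    fit_damped_cosine,
    phase_amplitude_summary,
)
from chronosim.synth import gen_actogram, gen_bioluminescence


class TestPeriodogram:
    def test_recovers_actogram_period_within_one_grid_step(self):
        acto = gen_actogram(period=23.8, days_LD=0, days_DD=14, mean_rate=2.0,
                            nocturnality=5.0, seed=42)
        est = estimate_free_running_period(acto, window_days=7)
        assert est.rhythmic
        assert est.period == pytest.approx(23.8, abs=0.1)

    def test_constant_series_nothing_significant(self):
        pg = chi_squared_periodogram(np.full(2000, 7.0), 0.1)
        assert np.all(pg.qp == 0.0)
        assert pg.best_period is None

    def test_square_wave_period_found_exactly_on_grid(self):
        # 24 h square wave in 0.1 h bins, 10 cycles
        K, N = 240, 10
        x = np.tile(np.repeat([0.0, 10.0], K // 2), N)
        pg = chi_squared_periodogram(x, 0.1, period_range=(20, 28))
        assert pg.best_period == pytest.approx(24.0, abs=1e-9)
        # folded-matched deterministic signal: Qp near its K*N ceiling
        j = np.argmin(np.abs(pg.test_periods - 24.0))
        assert pg.qp[j] > 0.95 * K * N

    def test_null_type_one_error_near_alpha(self):
        # single pre-registered 24 h period, Poisson noise
        rng = np.random.default_rng(7)
        hits = 0
        reps = 300
        for _ in range(reps):
            x = rng.poisson(12.0, size=1680).astype(float)
            pg = chi_squared_periodogram(x, 0.1, period_range=(23.95, 24.04))
            assert len(pg.test_periods) == 1
            hits += pg.best_period is not None
        assert 0.01 <= hits / reps <= 0.09

    def test_series_too_short_raises(self):
        with pytest.raises(ValueError, match="too short"):
            chi_squared_periodogram(np.ones(100), 0.1)

    def test_ld_segment_reads_24h(self):
        acto = gen_actogram(period=23.0, days_LD=10, days_DD=0, mean_rate=2.0,
                            nocturnality=5.0, seed=1)
        bpd = acto.bins_per_day
        seg = acto.counts[: 7 * bpd].astype(float)
        seg6 = seg.reshape(-1, 6).sum(axis=1)
        pg = chi_squared_periodogram(seg6, 0.1)
        # masking: the light cycle forces a 24 h rhythm regardless of the clock
        assert pg.best_period == pytest.approx(24.0, abs=0.1)

    def test_window_choice_stable(self):
        acto = gen_actogram(period=23.96, days_LD=0, days_DD=10, mean_rate=3.0,
                            nocturnality=6.0, seed=3)
        e7 = estimate_free_running_period(acto, window_days=7)
        e6 = estimate_free_running_period(acto, window_days=6)
        assert abs(e7.period - e6.period) <= 0.1 + 1e-9

    def test_no_dd_segment_raises(self):
        acto = gen_actogram(period=24.0, days_LD=5, days_DD=0, seed=0)
        with pytest.raises(ValueError, match="DD"):
            estimate_free_running_period(acto)


class TestDetrend:
    def test_removes_linear_drift_from_sinusoid(self):
        t = np.arange(0, 240, 0.1)
        drift = 0.3 * t
        x = np.cos(2 * np.pi * t / 24.0) + drift
        tt, d = detrend(t, x, window=24.0)
        dr = drift[(t >= tt[0]) & (t <= tt[-1])]
        corr = np.corrcoef(d, dr)[0, 1]
        assert abs(corr) < 0.05
        assert abs(d.mean()) < 0.05
        # the drift component itself is removed essentially exactly
        _, drift_resid = detrend(t, drift, window=24.0)
        assert np.abs(drift_resid).max() < 1e-9

    def test_constant_input_gives_zeros(self):
        t = np.arange(0, 96, 0.5)
        tt, d = detrend(t, np.full_like(t, 3.3), window=24.0)
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_integer_period_sinusoid_passes_through(self):
        t = np.arange(0, 240, 0.1)
        x = np.cos(2 * np.pi * t / 24.0)
        tt, d = detrend(t, x, window=24.0)
        ref = np.cos(2 * np.pi * tt / 24.0)
        rms = np.sqrt(np.mean((d - ref) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(ref ** 2)) + 0.02

    def test_idempotent_up_to_edges(self):
        rng = np.random.default_rng(0)
        t = np.arange(0, 240, 0.2)
        x = np.sin(2 * np.pi * t / 24.0) + 0.1 * t + rng.normal(0, 0.01, len(t))
        t1, d1 = detrend(t, x, window=24.0)
        t2, d2 = detrend(t1, d1, window=24.0)
        ref = d1[(t1 >= t2[0]) & (t1 <= t2[-1])]
        rms_diff = np.sqrt(np.mean((d2 - ref) ** 2))
        assert rms_diff < 0.01 * np.sqrt(np.mean(ref ** 2)) + 1e-9

    def test_linearity(self):
        t = np.arange(0, 96, 0.25)
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, len(t)))
        _, dx = detrend(t, x, 24.0)
        _, dy = detrend(t, y, 24.0)
        _, dxy = detrend(t, 2 * x + 3 * y, 24.0)
        assert np.allclose(dxy, 2 * dx + 3 * dy, atol=1e-10)

    def test_too_short_series_raises(self):
        t = np.arange(0, 40, 0.5)
        with pytest.raises(ValueError, match="duration"):
            detrend(t, np.sin(t), window=24.0)


class TestDampedCosineFit:
    def test_noiseless_recovery_is_exact(self):
        t, v = gen_bioluminescence(period=24.6, amplitude=4.0, damping_rate=0.0,
                                   drift_slope=0.0, noise_sd=0.0, days=5)
        fit = fit_damped_cosine(t, v)
        assert not fit["degenerate"]
        assert fit["period"] == pytest.approx(24.6, rel=1e-4)
        assert fit["damping_rate"] < 1e-4

    def test_recovery_under_noise(self):
        t, v = gen_bioluminescence(period=24.0, amplitude=5.0,
                                   damping_rate=0.01, noise_sd=0.25,
                                   days=6, seed=11)
        fit = fit_damped_cosine(t, v)
        assert fit["period"] == pytest.approx(24.0, rel=0.01)
        assert fit["damping_rate"] == pytest.approx(0.01, rel=0.2)

    def test_flat_input_flagged_degenerate(self):
        t = np.arange(0, 96, 0.25)
        fit = fit_damped_cosine(t, np.full_like(t, 2.0))
        assert fit["degenerate"]

    def test_period_recovery_unbiased(self):
        # |mean bias| < 0.5% at 10% noise over replicates
        errs = []
        for seed in range(25):
            t, v = gen_bioluminescence(period=23.5, amplitude=5.0,
                                       damping_rate=0.005, noise_sd=0.5,
                                       days=6, seed=seed)
            fit = fit_damped_cosine(t, v)
            errs.append(fit["period"] / 23.5 - 1.0)
        assert abs(np.mean(errs)) < 0.005

    def test_deterministic(self):
        t, v = gen_bioluminescence(period=25.0, amplitude=3.0, noise_sd=0.3,
                                   days=5, seed=5)
        f1 = fit_damped_cosine(t, v)
        f2 = fit_damped_cosine(t, v)
        assert f1 == f2


def _cosine_trajectory():
    t = np.arange(0, 240, 0.1)
    per = 24.0
    a = 2.0 + np.cos(2 * np.pi * t / per)            # peaks at t = 0 mod 24
    b = 2.0 + np.cos(2 * np.pi * (t - 12.0) / per)   # 12 h later
    c = 2.0 + 0.2 * np.cos(2 * np.pi * (t - 9.0) / per)
    return Trajectory(t, np.column_stack([a, b, c]), ["ref", "anti", "weak"])


class TestPhaseAmplitude:
    def test_variable_vs_itself_zero_phase_difference(self):
        traj = _cosine_trajectory()
        summ, diff = phase_amplitude_summary(traj, "ref", "ref")
        assert summ.rhythmic
        assert diff == pytest.approx(0.0, abs=0.05)

    def test_antiphase_pair_reports_half_cycle(self):
        traj = _cosine_trajectory()
        summ, diff = phase_amplitude_summary(traj, "anti", "ref")
        assert abs(diff) == pytest.approx(12.0, abs=0.2)

    def test_amplitude_ordering_and_phase_lead(self):
        traj = _cosine_trajectory()
        s_anti, _ = phase_amplitude_summary(traj, "anti", "ref")
        s_weak, _ = phase_amplitude_summary(traj, "weak", "ref")
        assert s_anti.relative_amplitude > s_weak.relative_amplitude

    def test_wrapping_convention(self):
        assert circular_phase_diff(2.0, 20.0) == pytest.approx(6.0)
        assert circular_phase_diff(20.0, 2.0) == pytest.approx(-6.0)
        assert circular_phase_diff(18.0, 6.0) == pytest.approx(12.0)

    def test_interpolated_peaks_beat_grid_resolution(self):
        t = np.arange(0, 96, 0.5)
        x = np.cos(2 * np.pi * (t - 3.17) / 24.0)
        pk_t, pk_v = find_peaks_interp(t, x, min_separation=12.0)
        assert len(pk_t) >= 3
        offs = (pk_t - 3.17) % 24.0
        offs = np.minimum(offs, 24.0 - offs)
        assert np.max(offs) < 0.05
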