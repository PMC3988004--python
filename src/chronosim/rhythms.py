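"""Rhythm analysis: chi-squared periodogram, detrending, damped-cosine fits.

This is the analysis stack applied to behavioral actograms and
bioluminescence traces: the Sokolove--Bushell chi-squared periodogram for
free-running period estimation, running-mean detrending of drifting
bioluminescence baselines, exponentially damped cosine fitting for
damping-rate estimation, and phase/amplitude summaries of simulated
trajectories in circadian time (CT).

Conventions
-----------
* Phase of a cycle is the time of the interpolated maximum (not the center
  of mass).
* For model trajectories CT0 is the *Bmal1* mRNA peak (configurable);
  behavioral CT12 is activity onset.  One free-running period is mapped to
  24 CT hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares
from scipy.signal import find_peaks
from scipy.stats import chi2

__all__ = [
    "RhythmSummary",
    "PeriodogramResult",
    "chi_squared_periodogram",
    "estimate_free_running_period",
    "detrend",
    "fit_damped_cosine",
    "phase_amplitude_summary",
    "find_peaks_interp",
    "circular_phase_diff",
]


@dataclass
class RhythmSummary:
    """Summary of one rhythmic (or not) variable."""

    period: float | None = None
    relative_amplitude: float = 0.0   # (max - min) / mean over one cycle
    peak_phase: float | None = None   # CT hours in [0, 24)
    damping_rate: float | None = None  # 1/h, None if not damped
    rhythmic: bool = False

    def to_dict(self) -> dict:
        return {
            "period_h": None if self.period is None else round(self.period, 4),
            "relative_amplitude": round(self.relative_amplitude, 4),
            "peak_phase_ct": (None if self.peak_phase is None
                              else round(self.peak_phase, 3)),
            "damping_rate_per_h": (None if self.damping_rate is None
                                   else round(self.damping_rate, 6)),
            "rhythmic": self.rhythmic,
        }


@dataclass
class PeriodogramResult:
    """Chi-squared periodogram over a grid of trial periods."""

    test_periods: np.ndarray
    qp: np.ndarray
    significance_line: np.ndarray
    best_period: float | None
    alpha: float

    @property
    def significant(self) -> np.ndarray:
        return self.qp > self.significance_line

    def to_tsv(self, path) -> None:
        sig = self.significant
        with open(path, "w") as fh:
            fh.write("period_h\tQp\tthreshold\tsignificant\n")
            for p, q, thr, s in zip(self.test_periods, self.qp,
                                    self.significance_line, sig):
                fh.write(f"{p:.6g}\t{q:.6g}\t{thr:.6g}\t{int(s)}\n")


# ---------------------------------------------------------------------------
# peak detection
# ---------------------------------------------------------------------------

def find_peaks_interp(times, x, min_separation=12.0, min_prominence=0.0):
    """Interpolated local maxima, at least ``min_separation`` hours apart.

    Discrete maxima are located first, then refined on a local cubic spline
    (derivative root within one sample of the discrete peak).  Ties are
    broken by earliest time.  Returns ``(peak_times, peak_values)``.
    """
    times = np.asarray(times, float)
    x = np.asarray(x, float)
    if len(times) < 5:
        return np.array([]), np.array([])
    dt = float(np.median(np.diff(times)))
    dist = max(1, int(round(min_separation / dt)))
    kwargs = {"distance": dist}
    if min_prominence > 0:
        kwargs["prominence"] = min_prominence
    idx, _ = find_peaks(x, **kwargs)
    pk_t, pk_v = [], []
    for i in idx:
        lo, hi = max(0, i - 3), min(len(x), i + 4)
        if hi - lo < 4:
            pk_t.append(times[i]); pk_v.append(x[i]); continue
        cs = CubicSpline(times[lo:hi], x[lo:hi])
        roots = cs.derivative().roots(extrapolate=False)
        roots = roots[(roots >= times[max(0, i - 1)]) & (roots <= times[min(len(x) - 1, i + 1)])]
        if len(roots):
            vals = cs(roots)
            j = int(np.argmax(vals))
            pk_t.append(float(roots[j])); pk_v.append(float(vals[j]))
        else:
            pk_t.append(times[i]); pk_v.append(x[i])
    return np.asarray(pk_t), np.asarray(pk_v)


# ---------------------------------------------------------------------------
# chi-squared periodogram (Sokolove-Bushell)
# ---------------------------------------------------------------------------

def chi_squared_periodogram(counts, bin_width_h, period_range=(20.0, 28.0),
                            alpha=0.05, bonferroni=False) -> PeriodogramResult:
    """Sokolove--Bushell chi-squared periodogram of an evenly binned series.

    For each trial period ``P`` (grid step = bin width) with ``K`` bins per
    cycle and ``N`` complete cycles, the first ``N*K`` points are folded
    into ``K`` columns with means ``M_h`` and grand mean ``M``::

        Qp = N * sum_h (M_h - M)^2 / sigma2_hat,
        sigma2_hat = sum_i (x_i - M)^2 / (K * N)

    i.e. the between-column sum of squares scaled so that, for white noise,
    ``Qp`` follows a chi-square distribution with K-1 degrees of freedom
    (each column mean has variance sigma^2/N).

    Under the null Qp ~ chi-square with K-1 degrees of freedom; the
    significance line is the upper-``alpha`` quantile (optionally
    Bonferroni-corrected across the period grid).  The best period is the
    one maximizing ``Qp - threshold`` among significant periods; a
    zero-variance series yields Qp = 0 everywhere and no best period.
    """
    x = np.asarray(counts, float)
    lo, hi = period_range
    k_lo = max(2, int(np.ceil(lo / bin_width_h)))
    k_hi = int(np.floor(hi / bin_width_h))
    if k_hi < k_lo:
        raise ValueError("period_range too narrow for this bin width")
    ks = np.arange(k_lo, k_hi + 1)
    periods = ks * bin_width_h
    if len(x) < 2 * k_hi:
        raise ValueError(
            f"series too short: need >= {2*k_hi} bins for the period grid"
        )
    n_tests = len(ks)
    a_eff = alpha / n_tests if bonferroni else alpha
    qp = np.zeros(len(ks))
    thr = np.array([chi2.ppf(1 - a_eff, k - 1) for k in ks])
    for j, K in enumerate(ks):
        N = len(x) // K
        seg = x[: N * K]
        M = seg.mean()
        denom = np.sum((seg - M) ** 2)
        if denom <= 0:
            qp[j] = 0.0
            continue
        col_means = seg.reshape(N, K).mean(axis=0)
        sigma2 = denom / (K * N)
        qp[j] = N * np.sum((col_means - M) ** 2) / sigma2
    excess = qp - thr
    sig = excess > 0
    best = float(periods[np.argmax(excess)]) if np.any(sig) else None
    return PeriodogramResult(periods, qp, thr, best, alpha)


def estimate_free_running_period(actogram, window_days=7, rebin_min=6,
                                 period_range=(20.0, 28.0),
                                 alpha=0.05) -> RhythmSummary:
    """Free-running period from the first days of constant darkness.

    Restricts the actogram to the first ``window_days`` days of DD, rebins
    the event counts to ``rebin_min``-minute columns, and runs the
    chi-squared periodogram over 20--28 h.
    """
    schedule = list(actogram.schedule)
    dd_days = [i for i, lab in enumerate(schedule) if lab == "DD"]
    if not dd_days:
        raise ValueError("actogram has no DD segment")
    if len(dd_days) < window_days:
        raise ValueError(
            f"need >= {window_days} DD days, actogram has {len(dd_days)}"
        )
    first = dd_days[0]
    bins_per_day = int(24 * 60 / actogram.bin_width)
    counts = np.asarray(actogram.counts, float)
    seg = counts[first * bins_per_day: (first + window_days) * bins_per_day]
    group = int(round(rebin_min / actogram.bin_width))
    if group > 1:
        usable = (len(seg) // group) * group
        seg = seg[:usable].reshape(-1, group).sum(axis=1)
        bw_h = group * actogram.bin_width / 60.0
    else:
        bw_h = actogram.bin_width / 60.0
    pg = chi_squared_periodogram(seg, bw_h, period_range=period_range, alpha=alpha)
    if pg.best_period is None:
        return RhythmSummary(rhythmic=False)
    # fold at the best period for a relative-amplitude estimate
    K = int(round(pg.best_period / bw_h))
    N = len(seg) // K
    prof = seg[: N * K].reshape(N, K).mean(axis=0)
    mean = prof.mean()
    rel = float((prof.max() - prof.min()) / mean) if mean > 0 else 0.0
    return RhythmSummary(period=pg.best_period, relative_amplitude=rel,
                         rhythmic=True)


# ---------------------------------------------------------------------------
# detrending
# ---------------------------------------------------------------------------

def detrend(times, values, window=24.0):
    """Subtract a centered running mean of width ``window`` hours.

    The output is shortened by half a window at each edge (only positions
    with a complete window are kept), so the result has mean ~ 0 and no
    baseline drift slower than the window.  Returns ``(times, detrended)``.
    """
    times = np.asarray(times, float)
    values = np.asarray(values, float)
    if len(times) < 2:
        raise ValueError("series too short to detrend")
    dt = float(np.median(np.diff(times)))
    span = times[-1] - times[0]
    if span < 2 * window:
        raise ValueError(
            f"series duration {span:.1f} h must be >= twice the window "
            f"({2*window:.1f} h)"
        )
    w = int(round(window / dt))
    if w % 2 == 0:
        w += 1
    kernel = np.ones(w) / w
    running = np.convolve(values, kernel, mode="valid")
    half = (w - 1) // 2
    trimmed_t = times[half: len(times) - half]
    out = values[half: len(values) - half] - running
    return trimmed_t, out


# ---------------------------------------------------------------------------
# damped cosine fit
# ---------------------------------------------------------------------------

def _damped_design(t, period, lam):
    om = 2 * np.pi / period
    e = np.exp(-lam * t)
    return np.column_stack([np.ones_like(t), e * np.cos(om * t), e * np.sin(om * t)])


def _linear_fit(t, x, period, lam):
    A = _damped_design(t, period, lam)
    coef, *_ = np.linalg.lstsq(A, x, rcond=None)
    resid = x - A @ coef
    return coef, float(np.sqrt(np.mean(resid ** 2)))


def fit_damped_cosine(times, values):
    """Least-squares fit of ``b + A exp(-lambda t) cos(2 pi t / P + phi)``.

    The nonlinear parameters (P, lambda) are fit by Levenberg--Marquardt
    from a documented deterministic multi-start grid (periods: dominant FFT
    period and 16..32 h in 4-h steps; damping: 0, 0.005, 0.02 per hour),
    with the linear parameters solved exactly at each step.  A flat input
    returns ``degenerate=True`` rather than raising.
    """
    t = np.asarray(times, float)
    x = np.asarray(values, float)
    t = t - t[0]
    if len(t) < 8 or np.ptp(x) <= 1e-12 * max(1.0, abs(np.mean(x))):
        return {"period": None, "damping_rate": None, "amplitude": 0.0,
                "phase": None, "baseline": float(np.mean(x)) if len(x) else 0.0,
                "rmse": 0.0, "degenerate": True}

    # FFT-based starting period
    dt = float(np.median(np.diff(t)))
    xf = x - x.mean()
    freqs = np.fft.rfftfreq(len(xf), dt)
    power = np.abs(np.fft.rfft(xf))
    power[0] = 0.0
    p_starts = [16.0, 20.0, 24.0, 28.0, 32.0]
    if np.any(power > 0):
        fdom = freqs[int(np.argmax(power))]
        if fdom > 0:
            p_fft = 1.0 / fdom
            if 2.0 < p_fft < t[-1]:
                p_starts = [p_fft] + p_starts
    lam_starts = [0.0, 0.005, 0.02]

    best = None
    for p0 in p_starts:
        for l0 in lam_starts:
            def resid(theta):
                period, lam = theta
                if period <= 1.0:
                    return np.full_like(x, 1e6)
                A = _damped_design(t, period, max(lam, 0.0))
                coef, *_ = np.linalg.lstsq(A, x, rcond=None)
                return x - A @ coef
            try:
                sol = least_squares(resid, x0=[p0, l0], method="lm",
                                    max_nfev=200)
            except Exception:
                continue
            period, lam = sol.x
            if period <= 1.0:
                continue
            lam = max(lam, 0.0)
            coef, rmse = _linear_fit(t, x, period, lam)
            if best is None or rmse < best[0] - 1e-12:
                best = (rmse, period, lam, coef)
    if best is None:
        return {"period": None, "damping_rate": None, "amplitude": 0.0,
                "phase": None, "baseline": float(np.mean(x)),
                "rmse": float(np.std(x)), "degenerate": True}
    rmse, period, lam, coef = best
    b, c1, c2 = coef
    amp = float(np.hypot(c1, c2))
    phase = float(np.arctan2(-c2, c1))
    return {"period": float(period), "damping_rate": float(lam),
            "amplitude": amp, "phase": phase, "baseline": float(b),
            "rmse": rmse, "degenerate": False}


# ---------------------------------------------------------------------------
# phase / amplitude summaries in circadian time
# ---------------------------------------------------------------------------

def circular_phase_diff(phase_a, phase_b, period=24.0):
    """Phase difference a - b wrapped into (-period/2, +period/2]."""
    d = (phase_a - phase_b) % period
    if d > period / 2:
        d -= period
    return d


def _last_peak(times, x, min_separation=12.0):
    pk_t, pk_v = find_peaks_interp(times, x, min_separation=min_separation)
    if len(pk_t) == 0:
        return None
    return float(pk_t[-1])


def trajectory_summary(times, x, verdict=None, ref=None, ct0_time=None,
                       period=None) -> RhythmSummary:
    """RhythmSummary for one trajectory column.

    ``verdict`` (a CycleVerdict) supplies classification and period;
    ``ct0_time`` (or a reference series ``ref`` whose last peak defines CT0)
    anchors the CT axis, with one period mapped to 24 CT hours.
    """
    rhythmic = verdict is not None and verdict.classification in ("sustained", "damped")
    per = period
    if per is None and verdict is not None:
        per = verdict.period
    phase = None
    if rhythmic and per:
        if ct0_time is None and ref is not None:
            ct0_time = _last_peak(times, ref, min_separation=0.5 * per)
        pk = _last_peak(times, x, min_separation=0.5 * per)
        if pk is not None:
            anchor = ct0_time if ct0_time is not None else 0.0
            phase = ((pk - anchor) % per) * 24.0 / per
    rel = verdict.relative_amplitude if verdict is not None else 0.0
    damping = None
    if verdict is not None and verdict.classification == "damped":
        damping = verdict.damping_rate
    return RhythmSummary(period=per, relative_amplitude=rel, peak_phase=phase,
                         damping_rate=damping, rhythmic=rhythmic)


def phase_amplitude_summary(trajectory, variable, reference_variable,
                            settle=None, min_separation=None):
    """Peak phase and amplitude of one variable against a CT reference.

    Both series are taken from ``trajectory`` (a Trajectory object).  CT0
    is the reference variable's peak; one period maps to 24 CT hours;
    the phase difference (variable minus reference) is wrapped into
    (-12, +12] CT hours.  Returns ``(RhythmSummary, phase_difference_ct)``.
    An arrhythmic variable yields a summary with ``rhythmic=False`` and no
    phase.
    """
    times = trajectory.times
    if settle is None:
        settle = times[0] + 0.6 * (times[-1] - times[0])
    m = times >= settle
    tt = times[m]
    x = trajectory.column(variable)[m]
    r = trajectory.column(reference_variable)[m]

    from .dynamics import classify_cycles  # late import avoids a cycle
    vx = classify_cycles(tt, x)
    vr = classify_cycles(tt, r)
    if vx.classification == "arrhythmic" or vx.period is None:
        return RhythmSummary(rhythmic=False), None
    per = vx.period
    sep = min_separation if min_separation is not None else 0.5 * per
    ct0 = _last_peak(tt, r, min_separation=sep) if vr.period else None
    pk = _last_peak(tt, x, min_separation=sep)
    phase = None
    diff = None
    if pk is not None and ct0 is not None:
        phase = ((pk - ct0) % per) * 24.0 / per
        diff = circular_phase_diff(phase, 0.0)
    elif pk is not None:
        phase = (pk % per) * 24.0 / per
    rel = _relative_amplitude_cycle(tt, x, per)
    return (RhythmSummary(period=per, relative_amplitude=rel, peak_phase=phase,
                          damping_rate=vx.damping_rate
                          if vx.classification == "damped" else None,
                          rhythmic=True), diff)


def _relative_amplitude_cycle(times, x, period):
    """(max - min) / mean over the last full cycle."""
    t_end = times[-1]
    m = times >= t_end - period
    seg = x[m]
    mean = float(np.mean(seg))
    if mean == 0:
        return 0.0
    return float((np.max(seg) - np.min(seg)) / abs(mean))
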