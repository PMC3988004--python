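"""Synthetic recordings emulating the standard circadian assay designs.

Three generators, all pure functions of their parameters and a seed:

* :func:`gen_actogram` -- locomotor activity as infrared beam-break events
  in 1-min bins, entrained to a 12:12 light-dark (LD) cycle and then
  free-running in constant darkness (DD).  The underlying rate is a
  two-level (day/night) profile with ~1-h sigmoidal transitions, so the
  expected dark-phase share of activity has a closed form.
* :func:`gen_bioluminescence` -- a *Per2/Bmal1* reporter trace in kcpm:
  damped cosine plus linear baseline drift plus Gaussian noise, the kind of
  trace that requires detrending before period analysis.
* :func:`gen_qpcr_timecourse` -- qPCR sampling of a simulated mRNA every
  4 h from CT0 in triplicate, with multiplicative lognormal noise and the
  "maximum mRNA amount set to 100" normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .rhythms import find_peaks_interp

__all__ = [
    "Actogram",
    "SamplingDesign",
    "gen_actogram",
    "gen_bioluminescence",
    "gen_qpcr_timecourse",
    "activity_rate_profile",
    "expected_actogram_counts",
]

# logistic time constant giving a 10-90% transition of ~1 h
_SIGMOID_TAU = 1.0 / np.log(81.0)


@dataclass
class Actogram:
    """Event counts per bin over consecutive days, with lighting labels."""

    bin_width: float              # minutes
    counts: np.ndarray            # non-negative integers
    schedule: list                # per-day labels: "LD" or "DD"

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        expected = int(round(len(self.schedule) * 24 * 60 / self.bin_width))
        if len(self.counts) != expected:
            raise ValueError(
                f"counts length {len(self.counts)} != days*24*60/bin_width = {expected}"
            )
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def days(self) -> int:
        return len(self.schedule)

    @property
    def bins_per_day(self) -> int:
        return int(round(24 * 60 / self.bin_width))


@dataclass
class SamplingDesign:
    """qPCR sampling design: every ``interval`` h from CT ``start``."""

    start: float = 0.0            # CT hours
    interval: float = 4.0         # hours
    replicates: int = 3
    normalization: str = "max100"  # or "none"

    def __post_init__(self):
        if self.interval <= 0 or 24.0 % self.interval != 0:
            raise ValueError("interval must divide 24 h")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.normalization not in ("max100", "none"):
            raise ValueError(f"unknown normalization {self.normalization!r}")

    @property
    def ct_points(self) -> np.ndarray:
        n = int(24.0 / self.interval)
        return self.start + self.interval * np.arange(n)


# ---------------------------------------------------------------------------
# actograms
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _night_weight(phase_h):
    """Smooth periodic indicator of the night half-cycle [12, 24).

    Sum of logistic rise at phase 12 and fall at phase 24, plus the wrapped
    copy of the previous cycle's fall so the profile is continuous at 0/24.
    """
    p = phase_h
    return (_sigmoid((p - 12.0) / _SIGMOID_TAU) - _sigmoid((p - 24.0) / _SIGMOID_TAU)
            + _sigmoid((p + 12.0) / _SIGMOID_TAU) - _sigmoid(p / _SIGMOID_TAU))


def activity_rate_profile(period, days_LD, days_DD, mean_rate, nocturnality,
                          bin_width=1.0):
    """Expected event rate (counts/min) at each bin midpoint.

    During LD the animal is entrained: activity follows the lighting cycle
    (night = hours 12-24 of each day).  During DD the night marker
    free-runs at ``period``: subjective time advances by 24/period circadian
    hours per real hour, starting in phase with the last LD cycle.
    """
    if not (20.0 <= period <= 28.0):
        raise ValueError("period must be in [20, 28] h")
    if nocturnality < 1.0:
        raise ValueError("nocturnality must be >= 1")
    level_day = 2.0 * mean_rate / (1.0 + nocturnality)
    level_night = nocturnality * level_day
    bins_per_day = int(round(24 * 60 / bin_width))
    t = (np.arange((days_LD + days_DD) * bins_per_day) + 0.5) * bin_width / 60.0
    t_dd0 = days_LD * 24.0
    phase = np.where(t < t_dd0, t % 24.0, ((t - t_dd0) * 24.0 / period + 0.0) % 24.0)
    # DD phase continues the LD convention: subjective day starts at former
    # lights-on, so activity onset drifts by (period - 24) h per day
    w = _night_weight(phase)
    return level_day + (level_night - level_day) * w


def expected_actogram_counts(period, days_LD, days_DD, mean_rate, nocturnality,
                             bin_width=1.0):
    """Expected total event count (integral of the rate profile)."""
    rate = activity_rate_profile(period, days_LD, days_DD, mean_rate,
                                 nocturnality, bin_width)
    return float(rate.sum() * bin_width)


def gen_actogram(period=23.8, days_LD=14, days_DD=14, mean_rate=2.0,
                 nocturnality=5.0, seed=None, bin_width=1.0) -> Actogram:
    """Simulate a beam-break actogram: LD entrainment then DD free run.

    Counts per bin are Poisson with the rate from
    :func:`activity_rate_profile`; identical seeds give identical output.
    ``mean_rate`` is in counts/min averaged over the cycle; ``nocturnality``
    is the night/day rate ratio (>= 1), so during LD the expected dark-phase
    share of events is approximately nocturnality/(nocturnality + 1).
    """
    rate = activity_rate_profile(period, days_LD, days_DD, mean_rate,
                                 nocturnality, bin_width)
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * bin_width)
    schedule = ["LD"] * days_LD + ["DD"] * days_DD
    return Actogram(bin_width=bin_width, counts=counts, schedule=schedule)


# ---------------------------------------------------------------------------
# bioluminescence traces
# ---------------------------------------------------------------------------

def gen_bioluminescence(period=24.0, amplitude=5.0, damping_rate=0.0,
                        drift_slope=0.0, noise_sd=0.0, days=5,
                        sampling_min=10.0, baseline=10.0, phase=0.0,
                        seed=None):
    """Simulate a bioluminescence trace (kcpm).

    ``baseline + amplitude * exp(-damping_rate t) * cos(2 pi t/period + phase)
    + drift_slope * t + N(0, noise_sd)`` sampled every ``sampling_min``
    minutes for ``days`` days.  Returns ``(times_h, values_kcpm)``.
    """
    if days < 3:
        raise ValueError("need at least 3 days of recording")
    t = np.arange(0.0, days * 24.0, sampling_min / 60.0)
    clean = (baseline
             + amplitude * np.exp(-damping_rate * t)
             * np.cos(2 * np.pi * t / period + phase)
             + drift_slope * t)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        clean = clean + rng.normal(0.0, noise_sd, size=len(t))
    return t, clean


# ---------------------------------------------------------------------------
# qPCR time courses
# ---------------------------------------------------------------------------

def gen_qpcr_timecourse(trajectory, variable, design: SamplingDesign | None = None,
                        noise_cv=0.1, seed=None, ct_reference="Bmal1_mRNA",
                        settle=None) -> pd.DataFrame:
    """Sample a simulated mRNA like a qPCR time course.

    CT0 is anchored at the reference variable's peak (*Bmal1* mRNA by
    default) in the post-transient part of the trajectory; samples are taken
    every ``design.interval`` circadian hours with ``design.replicates``
    replicates carrying multiplicative lognormal noise of coefficient of
    variation ``noise_cv``.  With ``max100`` normalization the largest
    replicate-mean is scaled to exactly 100.

    Returns a tidy DataFrame with columns ``ct``, ``replicate``, ``value``.
    """
    design = design or SamplingDesign()
    times = trajectory.times
    if settle is None:
        settle = times[0] + 0.5 * (times[-1] - times[0])
    m = times >= settle
    tt = times[m]
    if tt[-1] - tt[0] < 26.0:
        raise ValueError("trajectory must span >= 24 h past the transient")
    x = trajectory.column(variable)[m]
    ref = trajectory.column(ct_reference)[m]

    from .dynamics import classify_cycles
    v = classify_cycles(tt, ref)
    period = v.period if v.period else 24.0
    pk_t, _ = find_peaks_interp(tt, ref, min_separation=0.5 * period)
    t0 = float(pk_t[0]) if len(pk_t) else float(tt[np.argmax(ref)])

    cts = design.ct_points
    sample_times = t0 + cts * period / 24.0
    # keep sampling inside the trajectory
    while sample_times[-1] > tt[-1] and t0 - period >= tt[0]:
        t0 -= period
        sample_times = t0 + cts * period / 24.0
    values = np.interp(sample_times, tt, x)

    rng = np.random.default_rng(seed)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        noise = rng.lognormal(-sigma ** 2 / 2.0, sigma,
                              size=(design.replicates, len(cts)))
    else:
        noise = np.ones((design.replicates, len(cts)))
    table = values[None, :] * noise
    if design.normalization == "max100":
        peak = table.mean(axis=0).max()
        if peak > 0:
            table = table * (100.0 / peak)
    rows = [
        {"ct": float(ct), "replicate": r + 1, "value": float(table[r, j])}
        for j, ct in enumerate(cts)
        for r in range(design.replicates)
    ]
    return pd.DataFrame(rows)
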