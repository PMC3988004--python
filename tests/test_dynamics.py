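"""ODE integration against closed-form oracles; cycle classification."""

import numpy as np
import pytest

from chronosim.dynamics import (
    CycleVerdict,
    IntegrationError,
    Trajectory,
    classify_cycles,
    integrate,
)
from chronosim.network import ModelSpec, Reaction, Species


def _single_decay_model(rate=0.5):
    return ModelSpec(
        species=[Species("X@cyt", "cytoplasm", "monomer")],
        reactions=[Reaction((("X@cyt", 1),), (), "deg_X", "X decay")],
        transcription_rules=[],
        parameters={"deg_X": rate},
    )


def _binding_model(kon=2.0, koff=0.5):
    return ModelSpec(
        species=[
            Species("A@nuc", "nucleus", "monomer"),
            Species("B@nuc", "nucleus", "monomer"),
            Species("A:B@nuc", "nucleus", "complex", ("A", "B")),
        ],
        reactions=[
            Reaction((("A@nuc", 1), ("B@nuc", 1)), (("A:B@nuc", 1),),
                     "kon", "binding"),
            Reaction((("A:B@nuc", 1),), (("A@nuc", 1), ("B@nuc", 1)),
                     "koff", "unbinding"),
        ],
        transcription_rules=[],
        parameters={"kon": kon, "koff": koff},
    )


class TestIntegrationOracles:
    def test_first_order_decay_matches_closed_form(self):
        traj = integrate(_single_decay_model(0.5), initial_state=[100.0],
                         t_end=2.0, step_out=0.5)
        x2 = traj.column("X@cyt")[-1]
        assert x2 == pytest.approx(100.0 * np.exp(-1.0), rel=1e-6)

    def test_binding_reaches_mass_action_equilibrium(self):
        kon, koff = 2.0, 0.5
        traj = integrate(_binding_model(kon, koff),
                         initial_state=[1.0, 0.7, 0.0], t_end=200.0)
        a, b, c = (traj.column(n)[-1] for n in ("A@nuc", "B@nuc", "A:B@nuc"))
        assert a * b / c == pytest.approx(koff / kon, rel=1e-4)

    def test_binding_conserves_totals(self):
        traj = integrate(_binding_model(), initial_state=[1.0, 0.7, 0.1],
                         t_end=50.0)
        total_a = traj.column("A@nuc") + traj.column("A:B@nuc")
        total_b = traj.column("B@nuc") + traj.column("A:B@nuc")
        assert np.allclose(total_a, total_a[0], rtol=1e-8, atol=1e-8)
        assert np.allclose(total_b, total_b[0], rtol=1e-8, atol=1e-8)

    def test_deterministic_given_identical_inputs(self):
        m = _binding_model()
        t1 = integrate(m, initial_state=[1.0, 0.5, 0.0], t_end=10.0)
        t2 = integrate(m, initial_state=[1.0, 0.5, 0.0], t_end=10.0)
        assert np.array_equal(t1.states, t2.states)

    def test_invalid_horizon_rejected(self):
        with pytest.raises(Exception):
            integrate(_single_decay_model(), t_end=0.0)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(Exception):
            integrate(_binding_model(), initial_state=[1.0])


class TestTrajectory:
    def test_row_count_must_match_times(self):
        with pytest.raises(ValueError):
            Trajectory(np.arange(3.0), np.zeros((4, 2)), ["a", "b"])

    def test_times_strictly_increasing(self):
        with pytest.raises(ValueError):
            Trajectory(np.array([0.0, 1.0, 1.0]), np.zeros((3, 1)), ["a"])

    def test_window_selects_interval(self):
        traj = Trajectory(np.arange(0.0, 10.0), np.arange(10.0)[:, None], ["a"])
        w = traj.window(t_min=3.0, t_max=7.0)
        assert w.times[0] == 3.0 and w.times[-1] == 7.0


class TestClassification:
    def _series(self, lam, days=10, per=24.0):
        t = np.arange(0, days * 24, 0.05)
        x = 2.0 + np.exp(-lam * t) * np.cos(2 * np.pi * t / per)
        return t, x

    def test_sustained_cosine(self):
        t, x = self._series(0.0)
        v = classify_cycles(t, x)
        assert v.classification == "sustained"
        assert v.period == pytest.approx(24.0, abs=0.05)
        assert v.damping_rate == pytest.approx(0.0, abs=1e-4)

    def test_damped_cosine_with_rate_recovered(self):
        t, x = self._series(0.01, days=15)
        v = classify_cycles(t, x)
        assert v.classification == "damped"
        assert v.period == pytest.approx(24.0, abs=0.2)
        assert v.damping_rate == pytest.approx(0.01, rel=0.3)

    def test_monotone_series_arrhythmic(self):
        t = np.arange(0, 240, 0.05)
        v = classify_cycles(t, 5.0 * np.exp(-0.05 * t) + 1.0)
        assert v.classification == "arrhythmic"
        assert v.period is None

    def test_tiny_amplitude_is_arrhythmic(self):
        t = np.arange(0, 240, 0.05)
        x = 10.0 + 1e-6 * np.cos(2 * np.pi * t / 24.0)
        v = classify_cycles(t, x)
        assert v.classification == "arrhythmic"

    def test_fast_damping_with_few_peaks_uses_fallback(self):
        # only ~2 visible cycles before flattening: damped-fit fallback
        t = np.arange(0, 240, 0.05)
        x = 2.0 + np.exp(-0.08 * t) * np.cos(2 * np.pi * t / 24.0)
        v = classify_cycles(t, x)
        assert v.classification == "damped"
        assert (v.damping_rate or 0) > 1e-3

    def test_verdict_invariant_sustained_means_no_damping(self):
        t, x = self._series(0.0)
        v = classify_cycles(t, x)
        assert v.classification != "sustained" or abs(v.damping_rate) < 1e-3
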