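"""Summary-extraction tests: extrema, period, extinction, outcome labels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mplv.summaries import (
    Extremum,
    classify_outcome,
    estimate_period,
    extinction_time,
    find_extrema,
    invariant_drift,
    summarize,
)
from mplv.integrate import SolverSettings, Trajectory, simulate
from mplv.model import ModelParameters, State


def _ext(times, values, kind, series="x2"):
    return [Extremum(t, v, series, kind) for t, v in zip(times, values)]


class TestFindExtrema:
    def test_single_hump_refined_to_analytic_maximum(self):
        t = np.linspace(0.0, 6.0, 601)
        v = 100.0 * np.exp(-((t - 3.0) ** 2))
        ext = find_extrema(t, v)
        assert len(ext) == 1
        assert ext[0].kind == "max"
        assert ext[0].time == pytest.approx(3.0, abs=1e-6)
        assert ext[0].value == pytest.approx(100.0, rel=1e-6)

    def test_oscillation_alternates_and_orders(self):
        t = np.linspace(0.0, 10.0, 5001)
        ext = find_extrema(t, np.sin(2 * np.pi * t))
        kinds = [e.kind for e in ext]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))
        assert all(a.time < b.time for a, b in zip(ext, ext[1:]))

    def test_sign_flip_swaps_kinds_same_times(self):
        t = np.linspace(0.0, 10.0, 5001)
        v = np.sin(2 * np.pi * t) + 0.3 * np.sin(3 * np.pi * t)
        a = find_extrema(t, v)
        b = find_extrema(t, -v)
        assert len(a) == len(b)
        for ea, eb in zip(a, b):
            assert ea.time == pytest.approx(eb.time, abs=1e-9)
            assert {ea.kind, eb.kind} == {"max", "min"}

    def test_prominence_suppresses_ripple(self):
        t = np.linspace(0.0, 10.0, 5001)
        v = np.sin(2 * np.pi * t / 5) + 1e-3 * np.sin(40 * np.pi * t)
        ext = find_extrema(t, v, prominence_fraction=0.05)
        assert len([e for e in ext if e.kind == "max"]) == 2

    def test_short_or_invalid_input_rejected(self):
        with pytest.raises(ValueError):
            find_extrema([0.0, 1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            find_extrema([0, 1, 2], [1, 2, 1], prominence_fraction=1.5)


class TestPeriod:
    def test_mean_spacing(self):
        ext = _ext([1.0, 3.0, 5.0], [1, 1, 1], "max")
        assert estimate_period(ext) == pytest.approx(2.0)

    def test_single_maximum_has_no_period(self):
        assert estimate_period(_ext([1.0], [1.0], "max")) is None
        assert estimate_period(_ext([1.0, 2.0], [1.0, 1.0], "min")) is None

    @settings(max_examples=30, derandomize=True)
    @given(shift=st.floats(-50.0, 50.0))
    def test_invariant_to_time_shift(self, shift):
        base = [1.0, 2.9, 5.1, 7.0]
        a = estimate_period(_ext(base, [1] * 4, "max"))
        b = estimate_period(_ext([t + shift for t in base], [1] * 4, "max"))
        assert a == pytest.approx(b)


class TestExtinctionTime:
    def test_step_series_interpolated_crossing(self):
        # series that is 5 until t = 2 and 0 afterwards crosses at t ~ 2
        t = np.array([0.0, 1.0, 2.0, 2.0001, 3.0, 4.0])
        v = np.array([5.0, 5.0, 5.0, 0.0, 0.0, 0.0])
        assert extinction_time(t, v, 1e-3) == pytest.approx(2.0, abs=1e-3)
        # the crossing is linearly interpolated between bracketing samples
        t2 = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
        v2 = np.array([5.0, 5.0, 5.0, 0.0, 0.0])
        assert extinction_time(t2, v2, 1e-3) == pytest.approx(
            2.0 + (5.0 - 1e-3) / 5.0, abs=1e-12
        )

    def test_none_when_series_ends_above_threshold(self):
        t = np.linspace(0, 1, 11)
        assert extinction_time(t, np.full(11, 2.0), 1.0) is None

    def test_recovery_after_dip_not_extinction(self):
        t = np.linspace(0, 4, 5)
        v = np.array([5.0, 0.0, 0.0, 3.0, 3.0])
        assert extinction_time(t, v, 1.0) is None

    @pytest.mark.parametrize("thresholds", [(1e-4, 1e-3, 1e-2, 0.5)])
    def test_monotone_nonincreasing_in_threshold(self, thresholds):
        t = np.linspace(0.0, 20.0, 2001)
        v = 10.0 * np.exp(-t)  # monotone decay
        times = [extinction_time(t, v, th) for th in thresholds]
        assert all(a >= b for a, b in zip(times, times[1:]))


class TestClassifyOutcome:
    def test_both_extinct_when_both_cross(self):
        assert classify_outcome(8.0, 5.0, [], []) == "both_extinct"

    def test_predator_only(self):
        assert classify_outcome(None, 5.0, [], []) == "predator_extinct"

    def test_predator_crossing_with_prey_collapse_is_double_loss(self):
        assert (
            classify_outcome(None, 5.0, [], [], prey_terminal_collapse=True)
            == "both_extinct"
        )

    def test_declining_predator_trough_envelope(self):
        pred = _ext([1, 3, 5, 7, 9], [9.0, 7.0, 5.5, 4.5, 4.0], "min")
        prey = _ext([1, 3, 5, 7, 9], [10.0, 10.1, 10.0, 10.2, 10.1], "min", "x1")
        assert classify_outcome(None, None, prey, pred) == "predator_extinct"

    def test_mild_trough_drift_is_coexistence(self):
        pred = _ext([1, 3, 5, 7, 9], [9.6, 9.5, 9.3, 9.1, 8.8], "min")
        assert classify_outcome(None, None, [], pred) == "coexistence"


class TestOnTrajectories:
    def test_toxin_free_cycle_summary(self, condition_a_run):
        _, stats = condition_a_run
        assert stats.outcome == "coexistence"
        assert stats.prey_extinction is None and stats.predator_extinction is None
        assert stats.period == pytest.approx(1.907, abs=0.01)
        peaks = [e.value for e in stats.peaks("x1")]
        troughs = [e.value for e in stats.troughs("x1")]
        # closed orbit: consecutive prey maxima within 1%
        assert np.ptp(peaks) / np.mean(peaks) < 0.01
        assert np.mean(peaks) == pytest.approx(278.2, abs=1.0)
        assert np.mean(troughs) == pytest.approx(9.7, abs=0.1)

    def test_asymmetric_run_prey_peaks_strictly_increase(self, asymmetric_run):
        _, stats = asymmetric_run
        peaks = [e.value for e in stats.peaks("x1")]
        assert len(peaks) >= 8
        assert all(a < b for a, b in zip(peaks, peaks[1:]))
        assert peaks[0] == pytest.approx(277.4, abs=1.0)

    def test_severe_run_is_double_collapse(self, severe_run):
        _, stats = severe_run
        assert stats.outcome == "both_extinct"
        assert stats.predator_extinction is not None

    def test_invariant_drift_diagnostics(self, condition_a_run):
        traj, _ = condition_a_run
        toxfree = ModelParameters().with_updates(S1=0, S2=0, g1=0, g2=0, k=0)
        assert invariant_drift(traj, toxfree) < 1e-4
        # constant trajectory at the fixed point: zero drift
        t = np.linspace(0, 1, 11)
        y = np.tile([80.0, 80.0, 0.0, 0.0], (11, 1))
        flat = Trajectory(t=t, y=y, settings=SolverSettings())
        assert invariant_drift(flat, toxfree) == pytest.approx(0.0, abs=1e-12)

    def test_invariant_drift_rejects_extinct_series(self):
        t = np.linspace(0, 1, 11)
        y = np.tile([80.0, 0.0, 0.0, 0.0], (11, 1))
        with pytest.raises(ValueError):
            invariant_drift(Trajectory(t=t, y=y, settings=SolverSettings()),
                            ModelParameters())
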