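import numpy as np
import pytest

from gateqa.breathing import BreathingTrace, Cos4Spec, generate_pattern
from gateqa.gating import (
    GateSignal,
    GateWindow,
    LatencyModel,
    apply_latency,
    ct_to_gatert,
    duty_cycle,
    gate_signal,
    read_gate,
    residual_motion,
    window_thresholds,
    write_gate,
)

# fraction of the period with cos^4(u) < 0.3: root of cos^4(u) = 0.3
ON_FRACTION = 1.0 - 2.0 * np.arccos(0.3 ** 0.25) / np.pi  # 0.530427...


class TestPhaseMapping:
    @pytest.mark.parametrize("ct, branch, absolute, relative", [
        (30.0, "exhale", 15.0, 15.0),
        (30.0, "inhale", 65.0, 15.0),
        (100.0, "exhale", 50.0, 50.0),
        (100.0, "inhale", 100.0, 50.0),
        (20.0, "exhale", 10.0, 10.0),
        (20.0, "inhale", 60.0, 10.0),
        (0.0, "exhale", 0.0, 0.0),
    ])
    def test_mapping(self, ct, branch, absolute, relative):
        m = ct_to_gatert(ct, branch)
        assert m.absolute_pct == absolute
        assert m.branch_relative_pct == relative

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ct_to_gatert(120.0, "inhale")

    def test_roundtrip_via_gatert_constructor(self):
        w = GateWindow.from_gatert(15.0, 65.0)
        assert (w.exhale_pct, w.inhale_pct) == (30.0, 30.0)


class TestWindowThresholds:
    @pytest.mark.parametrize("window, expected", [
        ((30.0, 30.0), (6.0, 6.0)),
        ((100.0, 100.0), (20.0, 20.0)),
        ((0.0, 0.0), (0.0, 0.0)),
    ])
    def test_thresholds(self, window, expected):
        assert window_thresholds(GateWindow(*window), 20.0) == expected

    def test_requires_positive_amplitude(self):
        with pytest.raises(ValueError):
            window_thresholds(GateWindow(30.0, 30.0), 0.0)


class TestGateSignal:
    def test_reference_on_fraction(self, cos4_trace, reference_gate):
        frac, mean_on = duty_cycle(reference_gate, 4.0)
        assert frac == pytest.approx(ON_FRACTION, abs=1e-4)
        assert mean_on == pytest.approx(4.0 * ON_FRACTION, abs=5e-4)

    def test_gate_boundaries_sit_on_the_threshold(self, cos4_trace,
                                                  reference_gate):
        for a, b in reference_gate.steady_intervals():
            assert cos4_trace.interp([a])[0] == pytest.approx(6.0, abs=0.01)
            assert cos4_trace.interp([b])[0] == pytest.approx(6.0, abs=0.01)

    def test_fully_open_window_stays_on(self, cos4_trace):
        # thresholds at the learned peak: the gate closes only in the
        # immediate neighbourhood of each peak
        gate = gate_signal(cos4_trace, GateWindow(100.0, 100.0))
        frac, _ = duty_cycle(gate, 4.0)
        assert frac == pytest.approx(1.0, abs=0.01)

    def test_always_on_signal_saturates_duty_cycle(self):
        always_on = GateSignal(np.array([[0.0, 40.0]]))
        assert duty_cycle(always_on, 4.0)[0] == 1.0

    def test_closed_window_never_opens(self, cos4_trace):
        gate = gate_signal(cos4_trace, GateWindow(0.0, 0.0))
        assert len(gate) == 0 and gate.status == "never_crossed"

    def test_flat_trace_rejected(self):
        t = np.arange(0, 30, 0.01)
        with pytest.raises(ValueError):
            gate_signal(BreathingTrace(t, np.ones_like(t)),
                        GateWindow(30.0, 30.0))

    def test_no_intervals_during_learning(self, reference_gate):
        assert np.all(reference_gate.intervals[:, 0]
                      >= reference_gate.learning_end)

    def test_duty_cycle_monotone_in_window_bounds(self, cos4_trace):
        fracs = [duty_cycle(gate_signal(cos4_trace, GateWindow(e, 30.0)),
                            4.0)[0] for e in (10.0, 20.0, 30.0, 50.0, 80.0)]
        assert np.all(np.diff(fracs) >= 0)
        fracs = [duty_cycle(gate_signal(cos4_trace, GateWindow(30.0, i)),
                            4.0)[0] for i in (10.0, 20.0, 30.0, 50.0, 80.0)]
        assert np.all(np.diff(fracs) >= 0)

    def test_time_phase_convention_gives_half_period(self, cos4_trace):
        gate = gate_signal(cos4_trace,
                           GateWindow(30.0, 30.0, convention="time_phase"))
        frac, mean_on = duty_cycle(gate, 4.0)
        assert frac == pytest.approx(0.5, abs=1e-3)
        # distinct from the amplitude-threshold duty cycle
        assert abs(frac - ON_FRACTION) > 0.02


class TestLatency:
    def test_zero_latency_is_identity(self, reference_gate):
        out = apply_latency(reference_gate, LatencyModel(0.0, 0.0))
        assert np.allclose(out.intervals, reference_gate.intervals)

    def test_asymmetric_delays_shift_transitions(self):
        gate = GateSignal(np.array([[1.0, 3.0]]))
        out = apply_latency(gate, LatencyModel(0.055, 0.050))
        assert out.intervals[0] == pytest.approx([1.055, 3.050])
        assert (out.intervals[0, 1] - out.intervals[0, 0]
                == pytest.approx(1.995))

    def test_equal_delays_preserve_durations(self, reference_gate):
        out = apply_latency(reference_gate, LatencyModel(0.08, 0.08))
        assert np.allclose(out.intervals[:, 1] - out.intervals[:, 0],
                           reference_gate.intervals[:, 1]
                           - reference_gate.intervals[:, 0])

    def test_long_on_delay_drops_interval(self):
        gate = GateSignal(np.array([[1.0, 2.0]]))
        out = apply_latency(gate, LatencyModel(1.5, 0.0))
        assert len(out) == 0


class TestDutyAndResidual:
    def test_reference_duty_cycle_numbers(self, reference_gate):
        frac, mean_on = duty_cycle(reference_gate, 4.0)
        assert round(mean_on, 2) == 2.12
        assert round(100.0 * frac) == 53

    def test_reference_residual_motion(self, cos4_trace, reference_gate):
        assert residual_motion(cos4_trace, reference_gate) == pytest.approx(
            6.0, abs=0.01)

    def test_always_on_residual_is_full_amplitude(self, cos4_trace):
        gate = gate_signal(cos4_trace, GateWindow(100.0, 100.0))
        assert residual_motion(cos4_trace, gate) == pytest.approx(20.0,
                                                                  abs=0.01)

    def test_empty_gate(self, cos4_trace):
        empty = GateSignal(np.empty((0, 2)))
        assert duty_cycle(empty, 4.0) == (0.0, 0.0)
        assert residual_motion(cos4_trace, empty) == 0.0

    def test_residual_bounded_by_threshold(self, cos4_trace):
        # symmetric noise-free window: residual equals the open threshold
        for pct in (20.0, 40.0, 60.0):
            gate = gate_signal(cos4_trace, GateWindow(pct, pct))
            thr = pct / 100.0 * 20.0
            assert residual_motion(cos4_trace, gate) == pytest.approx(
                thr, abs=0.02)


def test_gate_csv_roundtrip(tmp_path, reference_gate):
    path = tmp_path / "gate.csv"
    write_gate(reference_gate, path)
    back = read_gate(path)
    assert np.allclose(back.intervals, reference_gate.intervals)
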