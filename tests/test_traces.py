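"""Force-trace estimators: offsets, binding detection, plateaus, stopping force."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from slideforce import (
    ForceTrace,
    KB,
    SimConfig,
    TraceAnnotation,
    analyze_trace,
    detect_binding,
    detect_binding_events,
    detect_plateau,
    estimate_offset,
    estimate_stiffness_equipartition,
    preset_config,
    simulate_trap_trace,
    stopping_force_from_plateau,
)


def _constant_trace(fx, fy, n=2000, fs=1000.0, k=0.05):
    t = np.arange(n) / fs
    return ForceTrace(
        time=t,
        force_x=np.full(n, float(fx)),
        force_y=np.full(n, float(fy)),
        trap_stiffness=k,
    )


def _plateau_trace(offset=(0.0, 0.0), plateau=(3.0, 4.0), n=6000, fs=1000.0):
    """Baseline at `offset` for t<2s, step to offset+plateau afterwards."""
    t = np.arange(n) / fs
    fx = np.where(t < 2.0, offset[0], offset[0] + plateau[0])
    fy = np.where(t < 2.0, offset[1], offset[1] + plateau[1])
    return ForceTrace(time=t, force_x=fx, force_y=fy, trap_stiffness=0.05)


_ANNOT = TraceAnnotation(
    baseline_window=(0.0, 1.9), binding_time=2.0, plateau_window=(2.5, 5.9)
)


class TestOffset:
    def test_constant_trace_offsets_recovered_exactly(self):
        trace = _constant_trace(1.0, -2.0)
        assert estimate_offset(trace, (0.0, 1.0)) == (1.0, -2.0)

    def test_simulated_free_bead_offset_within_three_se(self):
        cfg = SimConfig(seed=21, binding_time=None, duration=20.0,
                        offset_force=(0.5, 0.0))
        trace = simulate_trap_trace(cfg)
        ox, oy = estimate_offset(trace, (0.0, 20.0 - trace.dt))
        # samples are nearly independent at 1 kHz (bead relaxation ~0.2 ms)
        se = np.sqrt(0.05 * KB * 298.0 / trace.n_samples)
        assert abs(ox - 0.5) < 3 * se
        assert abs(oy) < 3 * se

    def test_window_outside_range_and_too_few_samples(self):
        trace = _constant_trace(0.0, 0.0)
        with pytest.raises(ValueError):
            estimate_offset(trace, (-5.0, 1.0))
        with pytest.raises(ValueError):
            estimate_offset(trace, (0.0, 0.005))

    def test_annotation_rejects_baseline_overlapping_post_binding(self):
        with pytest.raises(ValueError):
            TraceAnnotation(
                baseline_window=(0.0, 3.0), binding_time=2.0, plateau_window=(2.5, 5.0)
            )


class TestBindingDetection:
    def test_pure_baseline_has_no_event(self):
        cfg = SimConfig(seed=2, binding_time=None, duration=30.0)
        assert detect_binding(simulate_trap_trace(cfg)) is None

    def test_binding_detected_within_one_second(self):
        cfg = preset_config("gliding", seed=8, duration=60.0, binding_time=30.0)
        t = detect_binding(simulate_trap_trace(cfg))
        assert t is not None and abs(t - 30.0) <= 1.0

    def test_two_binding_events_first_and_all(self):
        cfg = preset_config(
            "gliding", seed=5, duration=30.0, binding_time=8.0,
            detachment_force=8.0, rebind_delay=3.0,
        )
        trace = simulate_trap_trace(cfg)
        truth = trace.metadata["true_binding_times"]
        events = detect_binding_events(trace)
        assert len(events) >= 2
        assert abs(events[0] - truth[0]) <= 1.0
        assert abs(events[1] - truth[1]) <= 1.0
        assert detect_binding(trace) == events[0]


class TestPlateauDetection:
    def test_noise_free_plateau_covers_post_rise_window(self):
        trace = _plateau_trace()
        window = detect_plateau(trace, 2.0, baseline_s=1.5)
        assert window is not None
        start, end = window
        assert start <= 2.6
        assert end == pytest.approx(trace.time[-1], abs=0.01)

    def test_ramp_only_trace_yields_no_plateau(self):
        # attachment breaks while the force is still rising
        cfg = preset_config(
            "gliding", seed=13, duration=20.0, binding_time=8.0, detachment_force=7.0
        )
        trace = simulate_trap_trace(cfg)
        assert detect_plateau(trace, 8.0) is None

    def test_simulated_plateau_window_within_two_seconds(self):
        cfg = preset_config("gliding", seed=17, duration=30.0, binding_time=8.0)
        trace = simulate_trap_trace(cfg)
        window = detect_plateau(trace, 8.0)
        assert window is not None
        # the force is within 2% of plateau ~3 s after binding
        assert window[0] <= 8.0 + 2 + 2.0
        assert window[1] == pytest.approx(trace.time[-1], abs=0.1)


class TestStoppingForce:
    def test_pythagoras_three_four_five(self):
        res = stopping_force_from_plateau(_plateau_trace(), _ANNOT)
        assert res.stopping_force == pytest.approx(5.0)
        assert res.n_baseline > 0 and res.n_plateau > 0

    def test_plateau_equal_to_offset_gives_zero(self):
        trace = _plateau_trace(offset=(1.0, 1.0), plateau=(0.0, 0.0))
        res = stopping_force_from_plateau(trace, _ANNOT)
        assert res.stopping_force == pytest.approx(0.0, abs=1e-12)

    def test_simulated_gliding_trace_recovers_plateau_force(self):
        cfg = preset_config("gliding", seed=23, duration=30.0, binding_time=8.0)
        trace = simulate_trap_trace(cfg)
        res = analyze_trace(trace)
        # offset SE dominates the estimator noise on a deterministic plateau
        se = np.sqrt(0.05 * KB * 298.0 / res.n_baseline)
        assert abs(res.stopping_force - 10.0) < max(3 * se, 0.1)

    def test_short_plateau_window_rejected(self):
        ann = TraceAnnotation(
            baseline_window=(0.0, 1.9), binding_time=2.0, plateau_window=(2.5, 2.7)
        )
        with pytest.raises(ValueError):
            stopping_force_from_plateau(_plateau_trace(), ann)

    @given(
        angle=st.floats(0.0, 2 * np.pi),
        fx=st.floats(-10.0, 10.0),
        fy=st.floats(-10.0, 10.0),
    )
    def test_rotation_invariance_of_stopping_force(self, angle, fx, fy):
        trace = _plateau_trace(plateau=(fx, fy))
        base = stopping_force_from_plateau(trace, _ANNOT).stopping_force
        c, s = np.cos(angle), np.sin(angle)
        rotated = ForceTrace(
            time=trace.time,
            force_x=c * trace.force_x - s * trace.force_y,
            force_y=s * trace.force_x + c * trace.force_y,
            trap_stiffness=trace.trap_stiffness,
        )
        rot = stopping_force_from_plateau(rotated, _ANNOT).stopping_force
        assert rot == pytest.approx(base, abs=1e-9)

    @given(cx=st.floats(-20.0, 20.0), cy=st.floats(-20.0, 20.0))
    def test_offset_cancellation(self, cx, cy):
        trace = _plateau_trace()
        base = stopping_force_from_plateau(trace, _ANNOT).stopping_force
        shifted = ForceTrace(
            time=trace.time,
            force_x=trace.force_x + cx,
            force_y=trace.force_y + cy,
            trap_stiffness=trace.trap_stiffness,
        )
        assert stopping_force_from_plateau(
            shifted, _ANNOT
        ).stopping_force == pytest.approx(base, abs=1e-9)

    def test_noise_free_stopping_force_equals_drive(self):
        cfg = SimConfig(
            seed=0, temperature=0.0, duration=40.0, binding_time=5.0,
            unloaded_velocity=270.0, team_friction=0.037, transport_angle=0.7,
        )
        trace = simulate_trap_trace(cfg)
        ann = TraceAnnotation(
            baseline_window=(0.0, 4.5), binding_time=5.0, plateau_window=(30.0, 39.9)
        )
        res = stopping_force_from_plateau(trace, ann)
        assert res.stopping_force == pytest.approx(9.99, rel=1e-4)


def test_equipartition_stiffness_diagnostic():
    cfg = SimConfig(seed=31, binding_time=None, duration=30.0, trap_stiffness=0.08)
    trace = simulate_trap_trace(cfg)
    k_est = estimate_stiffness_equipartition(trace, (0.0, 30.0))
    assert k_est == pytest.approx(0.08, rel=0.05)
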