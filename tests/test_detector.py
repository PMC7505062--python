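"""Unit and property tests for the two-channel ratio trigger state machine."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perchtrap.detector import (
    DetectorConfig,
    SensorSample,
    TriggerEvent,
    detector_init,
    detector_step,
    instantaneous_ratio,
    run_detector,
)


def make_trace(ratios, s2=500, start=0):
    """Integer-ADC trace realizing the given s1/s2 ratios exactly."""
    return [
        SensorSample(start + i, int(round(r * s2)), s2) for i, r in enumerate(ratios)
    ]


def rect_trace(onset, perch_len, total, high=1.10):
    """Baseline ratio 1.0 with a rectangular step to ``high`` at ``onset``."""
    ratios = [1.0] * total
    for i in range(onset, min(onset + perch_len, total)):
        ratios[i] = high
    return make_trace(ratios)


class TestInstantaneousRatio:
    @pytest.mark.parametrize(
        "s1,s2,expected",
        [(512, 512, 1.0), (630, 600, 1.05), (100, 400, 0.25)],
    )
    def test_dark_high_division(self, s1, s2, expected):
        cfg = DetectorConfig()
        assert instantaneous_ratio(SensorSample(0, s1, s2), cfg) == pytest.approx(expected)

    def test_night_sample_gated_below_floor(self):
        cfg = DetectorConfig(signal_floor=8)
        assert instantaneous_ratio(SensorSample(0, 0, 500), cfg) is None
        assert instantaneous_ratio(SensorSample(0, 500, 3), cfg) is None

    def test_dark_low_polarity_inverts(self):
        cfg = DetectorConfig(polarity="dark_low")
        assert instantaneous_ratio(SensorSample(0, 400, 500), cfg) == pytest.approx(1.25)


class TestDetectorStep:
    def test_constant_trace_never_triggers(self):
        trace = make_trace([1.0] * 600)
        triggers, diag = run_detector(trace)
        assert triggers == []
        assert (diag.td_s == 0).all()

    def test_rectangular_step_reboot_then_shutter(self):
        # 60 s flat baseline, then ratio 1.10 for 15 s: reboot on the 7th
        # supra-threshold second, shutter on the 10th, nothing else
        trace = rect_trace(60, 15, 95)
        triggers, _ = run_detector(trace)
        assert triggers == [TriggerEvent(66, "reboot"), TriggerEvent(69, "shutter")]

    def test_step_shorter_than_Z_gives_no_shutter(self):
        triggers, _ = run_detector(rect_trace(60, 5, 95))
        assert [t for t in triggers if t.kind == "shutter"] == []

    def test_unordered_timestamps_rejected(self):
        cfg = DetectorConfig()
        state = detector_init(0)
        state, _ = detector_step(state, SensorSample(5, 500, 500), cfg)
        with pytest.raises(ValueError, match="strictly increasing"):
            detector_step(state, SensorSample(5, 500, 500), cfg)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            run_detector([])

    def test_one_shutter_per_bout_and_rearm(self):
        # two qualifying bouts separated by a single sub-threshold second
        ratios = [1.0] * 60 + [1.10] * 12 + [1.0] + [1.10] * 12 + [1.0] * 30
        triggers, _ = run_detector(make_trace(ratios))
        shutters = [t for t in triggers if t.kind == "shutter"]
        assert len(shutters) == 2

    def test_long_bout_takes_single_photo(self):
        triggers, _ = run_detector(rect_trace(60, 120, 240))
        assert sum(1 for t in triggers if t.kind == "shutter") == 1

    @pytest.mark.parametrize("onset", [61, 150, 292, 295, 299, 300, 301, 305, 500])
    def test_boundary_spanning_onsets_still_detected(self, onset):
        # the X = 300 s window reset must not erase a perch's reference
        # baseline, wherever the bout starts relative to the boundary
        trace = rect_trace(onset, 12, 650)
        triggers, _ = run_detector(trace)
        assert [t.kind for t in triggers] == ["reboot", "shutter"]
        assert triggers[1].time_s == onset + 9  # 10th supra-threshold sample

    def test_gated_samples_reset_td(self):
        ratios = [1.0] * 60 + [1.10] * 8
        trace = make_trace(ratios)
        trace.append(SensorSample(68, 0, 0))  # night dropout mid-bout
        trace += make_trace([1.10] * 5, start=69)
        triggers, _ = run_detector(trace)
        assert [t for t in triggers if t.kind == "shutter"] == []


class TestCommonModeInvariance:
    @given(
        scale=st.floats(min_value=0.05, max_value=20.0, allow_nan=False),
        onset=st.integers(min_value=40, max_value=120),
        length=st.integers(min_value=5, max_value=30),
    )
    @settings(max_examples=40)
    def test_scaling_both_channels_preserves_triggers(self, scale, onset, length):
        cfg = DetectorConfig(signal_floor=0.0)
        base = [
            SensorSample(i, 500.0 * (1.10 if onset <= i < onset + length else 1.0), 500.0)
            for i in range(200)
        ]
        scaled = [SensorSample(s.time_s, s.s1 * scale, s.s2 * scale) for s in base]
        t1, _ = run_detector(base, cfg)
        t2, _ = run_detector(scaled, cfg)
        assert t1 == t2


def oracle_detector(trace, cfg):
    """Brute-force re-simulation: the baseline mean is recomputed from the
    full list of window ratios at every sample."""
    triggers = []
    window = []
    window_start = trace[0].time_s
    td, armed, sub = 0, True, 0
    for s in trace:
        gated = s.s1 < cfg.signal_floor or s.s2 < cfg.signal_floor
        r = None if gated else (
            s.s1 / s.s2 if cfg.polarity == "dark_high" else s.s2 / s.s1
        )
        if r is None:
            td = 0
            sub += 1
            if sub >= cfg.rearm_samples:
                armed = True
            if s.time_s - window_start >= cfg.reset_interval_X_s:
                window, window_start = [], s.time_s
            continue
        yt = r / (sum(window) / len(window)) if window else 1.0
        if yt >= cfg.ratio_threshold_Y:
            td += cfg.sample_period_s
            sub = 0
            if td == cfg.reboot_at_s:
                triggers.append(TriggerEvent(s.time_s, "reboot"))
            if td == cfg.perch_duration_Z_s and armed:
                triggers.append(TriggerEvent(s.time_s, "shutter"))
                armed = False
            if cfg.baseline_includes_perch:
                window.append(r)
        else:
            td = 0
            sub += 1
            if sub >= cfg.rearm_samples:
                armed = True
            window.append(r)
        if td == 0 and s.time_s - window_start >= cfg.reset_interval_X_s:
            window, window_start = [r], s.time_s
    return triggers


class TestOracleEquivalence:
    @pytest.mark.parametrize("include_perch", [False, True])
    @pytest.mark.parametrize("rearm", [1, 3])
    def test_matches_recompute_from_scratch_oracle(self, include_perch, rearm):
        import numpy as np

        cfg = DetectorConfig(
            reset_interval_X_s=50,
            baseline_includes_perch=include_perch,
            rearm_samples=rearm,
        )
        rng = np.random.default_rng(20_250_101)
        for _ in range(100):
            n = int(rng.integers(50, 200))
            s2 = rng.integers(400, 600, size=n)
            bumps = (rng.random(n) < 0.2) * rng.uniform(1.0, 1.3, size=n)
            s1 = np.clip((s2 * np.where(bumps > 0, bumps, 1.0)).astype(int), 0, 1023)
            # occasional night dropouts exercise the gating path
            dark = rng.random(n) < 0.05
            s1[dark] = 0
            trace = [SensorSample(i, int(a), int(b)) for i, (a, b) in enumerate(zip(s1, s2))]
            got, _ = run_detector(trace, cfg)
            assert got == oracle_detector(trace, cfg)


class TestConfigValidation:
    def test_parameter_ordering_enforced(self):
        with pytest.raises(ValueError):
            DetectorConfig(reboot_at_s=12)  # reboot after shutter threshold
        with pytest.raises(ValueError):
            DetectorConfig(ratio_threshold_Y=0.9)
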