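"""Perching-detection state machine for a two-sensor camera trap.

The trap watches the ratio of two photoresistor channels sampled once per
second: a top "detection" sensor exposed to direct sunlight and a lower
"reference" sensor behind a diffuser.  A perching dragonfly shades the top
sensor, so the instantaneous channel ratio rises relative to its recent
average.  The firmware parameters are conventionally called X (baseline
reset interval, 300 s), Y (ratio threshold, 1.05), Z (required perching
duration, 10 s) and Td (the running perch-duration counter; the sleeping
camera is sent a wake-up/reboot pulse when Td reaches 7 s so it is awake by
the time the shutter command arrives at Td = Z).

Using the ratio of *relative* signal values (instantaneous ratio divided by
its windowed average) makes the trigger insensitive to common-mode changes:
sensor gain differences, slow solar drift, and broad illumination changes
cancel, while an asymmetric occlusion of the top sensor does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "SensorSample",
    "DetectorConfig",
    "DetectorState",
    "TriggerEvent",
    "instantaneous_ratio",
    "detector_init",
    "detector_step",
    "run_detector",
]

ADC_MAX = 1023


@dataclass(frozen=True)
class SensorSample:
    """One 1-s reading of the two light channels.

    ``s1``/``s2`` are ADC counts in [0, 1023] on hardware; real-valued
    signals are accepted so that pre-quantization invariants (e.g.
    common-mode scaling) can be exercised directly.
    """

    time_s: int
    s1: float
    s2: float


@dataclass(frozen=True)
class DetectorConfig:
    """Firmware parameters of the detector.

    Defaults reproduce the field configuration: X = 300 s, Y = 1.05,
    Z = 10 s, camera reboot at Td = 7 s, 1-s sample cycle.

    ``signal_floor`` gates detection when either channel reads below it
    (night / disconnected-sensor guard; also removes any division by zero).
    ``polarity`` selects which channel rises when the top sensor is shaded:
    ``dark_high`` means darkness maps to high ADC counts (the ratio used is
    s1/s2), ``dark_low`` the opposite (s2/s1).  ``baseline_includes_perch``
    controls whether supra-threshold samples feed the baseline average;
    excluding them (default) prevents a long perch from eroding its own
    detectability.  ``rearm_samples`` consecutive sub-threshold samples
    re-arm the shutter after a photo, giving one image per perching bout.
    """

    reset_interval_X_s: int = 300
    ratio_threshold_Y: float = 1.05
    perch_duration_Z_s: int = 10
    reboot_at_s: int = 7
    sample_period_s: int = 1
    signal_floor: float = 8
    polarity: str = "dark_high"
    baseline_includes_perch: bool = False
    rearm_samples: int = 1

    def __post_init__(self) -> None:
        if not (0 < self.reboot_at_s < self.perch_duration_Z_s < self.reset_interval_X_s):
            raise ValueError(
                "require 0 < reboot_at_s < perch_duration_Z_s < reset_interval_X_s, got "
                f"{self.reboot_at_s}, {self.perch_duration_Z_s}, {self.reset_interval_X_s}"
            )
        if self.ratio_threshold_Y <= 1:
            raise ValueError("ratio_threshold_Y must exceed 1")
        if self.polarity not in ("dark_high", "dark_low"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.sample_period_s <= 0 or self.rearm_samples < 1:
            raise ValueError("sample_period_s must be positive and rearm_samples >= 1")


@dataclass
class DetectorState:
    """Evolving baseline / duration / arming state between samples."""

    window_start_s: int = 0
    baseline_sum: float = 0.0
    baseline_n: int = 0
    Td_s: int = 0
    armed: bool = True
    sub_threshold_run: int = 0
    last_time_s: int | None = None


@dataclass(frozen=True)
class TriggerEvent:
    """A camera command emitted by the detector."""

    time_s: int
    kind: str  # "reboot" | "shutter"


def instantaneous_ratio(sample: SensorSample, config: DetectorConfig) -> float | None:
    """Channel ratio for one sample, or ``None`` when gated.

    Returns s1/s2 under ``dark_high`` polarity (s2/s1 under ``dark_low``).
    Gated (``None``) whenever either channel is below ``signal_floor`` —
    the night/invalid guard, which also subsumes division by zero.
    """
    if sample.s1 < config.signal_floor or sample.s2 < config.signal_floor:
        return None
    if config.polarity == "dark_high":
        return sample.s1 / sample.s2
    return sample.s2 / sample.s1


def detector_init(first_time_s: int = 0) -> DetectorState:
    """Fresh state with the averaging window opening at ``first_time_s``."""
    return DetectorState(window_start_s=first_time_s)


def detector_step(
    state: DetectorState, sample: SensorSample, config: DetectorConfig
) -> tuple[DetectorState, list[TriggerEvent]]:
    """Advance the state machine by one 1-s sample.

    Per cycle: the instantaneous ratio is referenced to the arithmetic mean
    of ratios accumulated since the current window start (the relative
    indicator Yt; Yt := 1 while the window is empty).  Yt >= Y extends the
    perch counter Td and emits a reboot at Td = reboot_at_s and — if armed —
    a shutter at Td = Z, after which the detector disarms until
    ``rearm_samples`` consecutive sub-threshold samples have passed.
    Sub-threshold samples reset Td and feed the baseline.  The window is
    reset every X seconds, but the reset is postponed while Td > 0 so a
    perch spanning the boundary is still referenced to its pre-perch
    baseline; the new window is seeded with the current sub-threshold ratio.

    Returns a new state; the input state is not mutated.

    Raises ``ValueError`` on non-increasing timestamps.
    """
    t = sample.time_s
    if state.last_time_s is not None and t <= state.last_time_s:
        raise ValueError(
            f"sample times must be strictly increasing: got {t} after {state.last_time_s}"
        )

    new = DetectorState(
        window_start_s=state.window_start_s,
        baseline_sum=state.baseline_sum,
        baseline_n=state.baseline_n,
        Td_s=state.Td_s,
        armed=state.armed,
        sub_threshold_run=state.sub_threshold_run,
        last_time_s=t,
    )
    events: list[TriggerEvent] = []

    ratio = instantaneous_ratio(sample, config)
    if ratio is None:
        # Night/invalid: no detection, counts toward re-arming, skips baseline.
        new.Td_s = 0
        new.sub_threshold_run += 1
        if new.sub_threshold_run >= config.rearm_samples:
            new.armed = True
        if t - new.window_start_s >= config.reset_interval_X_s:
            new.window_start_s = t
            new.baseline_sum = 0.0
            new.baseline_n = 0
        return new, events

    yt = ratio / (new.baseline_sum / new.baseline_n) if new.baseline_n > 0 else 1.0

    if yt >= config.ratio_threshold_Y:
        new.Td_s += config.sample_period_s
        new.sub_threshold_run = 0
        if new.Td_s == config.reboot_at_s:
            events.append(TriggerEvent(t, "reboot"))
        if new.Td_s == config.perch_duration_Z_s and new.armed:
            events.append(TriggerEvent(t, "shutter"))
            new.armed = False
        if config.baseline_includes_perch:
            new.baseline_sum += ratio
            new.baseline_n += 1
    else:
        new.Td_s = 0
        new.sub_threshold_run += 1
        if new.sub_threshold_run >= config.rearm_samples:
            new.armed = True
        new.baseline_sum += ratio
        new.baseline_n += 1

    # X-interval window reset, postponed while a perch is in progress.  The
    # fresh window is seeded with the current sub-threshold ratio so the
    # next sample still has a reference (an empty window would force Yt = 1
    # and let a perch onset seed its own baseline).
    if new.Td_s == 0 and t - new.window_start_s >= config.reset_interval_X_s:
        new.window_start_s = t
        new.baseline_sum = ratio
        new.baseline_n = 1

    return new, events


def run_detector(
    trace: Iterable[SensorSample] | Sequence[SensorSample],
    config: DetectorConfig | None = None,
) -> tuple[list[TriggerEvent], pd.DataFrame]:
    """Run the detector over a whole trace.

    Returns the concatenated trigger events and a per-sample diagnostic
    DataFrame with columns ``time_s``, ``ratio``, ``yt``, ``td_s``,
    ``armed`` (ratio and yt are NaN for gated samples).

    Raises ``ValueError`` for an empty trace.
    """
    config = config or DetectorConfig()
    it = iter(trace)
    try:
        first = next(it)
    except StopIteration:
        raise ValueError("run_detector requires a non-empty trace") from None

    state = detector_init(first.time_s)
    triggers: list[TriggerEvent] = []
    rows: list[tuple] = []
    for sample in _chain_one(first, it):
        ratio = instantaneous_ratio(sample, config)
        if ratio is None:
            yt = None
        elif state.baseline_n > 0:
            yt = ratio / (state.baseline_sum / state.baseline_n)
        else:
            yt = 1.0
        state, events = detector_step(state, sample, config)
        triggers.extend(events)
        rows.append((sample.time_s, ratio, yt, state.Td_s, state.armed))

    diag = pd.DataFrame(rows, columns=["time_s", "ratio", "yt", "td_s", "armed"])
    return triggers, diag


def _chain_one(first, rest):
    yield first
    yield from rest
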