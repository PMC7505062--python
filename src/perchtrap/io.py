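"""CSV/JSON readers and writers for traces, triggers, frame logs, events,
truth schedules and detector configuration.

All timestamps are integer seconds from trace start.  Parse errors name the
offending row (1-based, counting the header as row 1).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .detector import ADC_MAX, DetectorConfig, SensorSample, TriggerEvent
from .events import FrameLog, PerchingEvent
from .simulator import PerchInterval

__all__ = [
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_triggers",
    "write_triggers",
    "read_frames",
    "write_frames",
    "write_events",
    "read_truth",
    "write_truth",
    "write_image_log",
    "read_image_log",
    "load_detector_config",
]


class TraceParseError(ValueError):
    """Malformed sensor-trace input; the message names the file row."""


def read_trace(path: str | Path) -> list[SensorSample]:
    """Read a sensor trace CSV (columns time_s, s1, s2; header required)."""
    df = pd.read_csv(path)
    required = ["time_s", "s1", "s2"]
    if list(df.columns[:3]) != required:
        raise TraceParseError(f"{path}: expected header time_s,s1,s2, got {list(df.columns)}")
    for col in required:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise TraceParseError(f"{path}: non-numeric {col} at row {bad[0] + 2}")
    for col in ("s1", "s2"):
        out = df.index[(df[col] < 0) | (df[col] > ADC_MAX)]
        if len(out):
            raise TraceParseError(
                f"{path}: {col}={df[col].iloc[out[0]]} out of range 0..{ADC_MAX} at row {out[0] + 2}"
            )
    t = df["time_s"].to_numpy()
    if len(t) > 1 and (t[1:] <= t[:-1]).any():
        row = int((t[1:] <= t[:-1]).argmax()) + 1
        raise TraceParseError(f"{path}: unordered time_s at row {row + 2}")
    return [
        SensorSample(int(r.time_s), int(r.s1), int(r.s2))
        for r in df.itertuples(index=False)
    ]


def write_trace(trace: Sequence[SensorSample], path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": [s.time_s for s in trace],
         "s1": [s.s1 for s in trace],
         "s2": [s.s2 for s in trace]}
    ).to_csv(path, index=False)


def read_triggers(path: str | Path) -> list[TriggerEvent]:
    df = pd.read_csv(path)
    if len(df) == 0:
        return []
    bad = ~df["kind"].isin(["reboot", "shutter"])
    if bad.any():
        row = int(bad.to_numpy().argmax())
        raise TraceParseError(f"{path}: unknown trigger kind at row {row + 2}")
    return [TriggerEvent(int(r.time_s), str(r.kind)) for r in df.itertuples(index=False)]


def write_triggers(triggers: Sequence[TriggerEvent], path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": [e.time_s for e in triggers], "kind": [e.kind for e in triggers]}
    ).to_csv(path, index=False)


def read_frames(path: str | Path, frame_interval_s: int = 10) -> FrameLog:
    df = pd.read_csv(path)
    return FrameLog(
        frames=tuple(
            (int(r.frame_time_s), bool(int(r.present))) for r in df.itertuples(index=False)
        ),
        frame_interval_s=frame_interval_s,
    )


def write_frames(frames: FrameLog, path: str | Path) -> None:
    pd.DataFrame(
        {"frame_time_s": [t for t, _ in frames.frames],
         "present": [int(p) for _, p in frames.frames]}
    ).to_csv(path, index=False)


def write_events(events: Sequence[PerchingEvent], path: str | Path) -> None:
    pd.DataFrame(
        {"start_s": [e.start_s for e in events],
         "end_s": [e.end_s for e in events],
         "n_present_frames": [e.n_present_frames for e in events],
         "duration_class": [e.duration_class for e in events]}
    ).to_csv(path, index=False)


def read_truth(path: str | Path) -> list[PerchInterval]:
    df = pd.read_csv(path)
    return [
        PerchInterval(float(r.start_s), float(r.end_s) - float(r.start_s), float(r.occlusion))
        for r in df.itertuples(index=False)
    ]


def write_truth(truth: Sequence[PerchInterval], path: str | Path) -> None:
    pd.DataFrame(
        {"start_s": [p.start_s for p in truth],
         "end_s": [p.end_s for p in truth],
         "occlusion": [p.occlusion for p in truth]}
    ).to_csv(path, index=False)


def write_image_log(images: Sequence[tuple[int, bool]], path: str | Path) -> None:
    pd.DataFrame(
        {"time_s": [t for t, _ in images],
         "dragonfly_present": [int(p) for _, p in images]}
    ).to_csv(path, index=False)


def read_image_log(path: str | Path) -> list[tuple[int, bool]]:
    df = pd.read_csv(path)
    return [
        (int(r.time_s), bool(int(r.dragonfly_present))) for r in df.itertuples(index=False)
    ]


def load_detector_config(path: str | Path | None) -> DetectorConfig:
    """Detector parameters from a JSON file keyed by DetectorConfig fields."""
    if path is None:
        return DetectorConfig()
    raw = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(DetectorConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"{path}: unknown detector config keys {sorted(unknown)}")
    return DetectorConfig(**raw)
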