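"""Field-validation analytics: image de-duplication, bout-criterion
perching-event extraction from time-lapse frame logs, and event–image
matching for sensitivity.

A "perching event" is a behavioural bout recovered from a 10-s time-lapse
record: a maximal run of dragonfly-present frames in which any internal
absent run is shorter than the bout criterion (two frames = 20 s).  An
absent gap of two or more consecutive frames closes the bout.  Sensitivity
is then TP / (TP + FN) over events, where an event is a true positive iff
at least one trap image of a dragonfly falls within its time span (plus a
small tolerance for clock skew).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

__all__ = [
    "FrameLog",
    "PerchingEvent",
    "MatchResult",
    "UndefinedSensitivityError",
    "deduplicate_images",
    "extract_perching_events",
    "classify_event_duration",
    "match_events",
]


class UndefinedSensitivityError(ValueError):
    """Raised when TP + FN = 0 and sensitivity has no value (no events at all)."""


@dataclass(frozen=True)
class FrameLog:
    """Ordered (frame_time_s, present) records at a fixed frame interval."""

    frames: tuple[tuple[int, bool], ...]
    frame_interval_s: int = 10

    def __post_init__(self) -> None:
        times = [t for t, _ in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")


@dataclass(frozen=True)
class PerchingEvent:
    start_s: int
    end_s: int
    n_present_frames: int
    duration_class: str  # "gt20s" | "le20s"


@dataclass(frozen=True)
class MatchResult:
    event_outcomes: tuple[str, ...]   # "true_positive" | "false_negative" per event
    image_outcomes: tuple[str, ...]   # "true_positive" | "false_positive" per image
    tp: int
    fn: int
    sensitivity: float | None

    @property
    def defined(self) -> bool:
        return self.sensitivity is not None


def deduplicate_images(image_times: Sequence[float], window_s: float = 5) -> list[float]:
    """Drop the earlier of any pair of consecutive images closer than ``window_s``.

    Applied left to right, so a burst t, t+2, t+4 collapses to the last
    image t+4 (each earlier photo of a near-duplicate pair is removed).
    """
    times = list(image_times)
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("image timestamps must be sorted")
    kept: list[float] = []
    for i, t in enumerate(times):
        if i + 1 < len(times) and times[i + 1] - t < window_s:
            continue
        kept.append(t)
    return kept


def extract_perching_events(frames: FrameLog, max_gap_frames: int = 2) -> list[PerchingEvent]:
    """Segment a frame log into bout-criterion perching events.

    Events are maximal runs of present frames whose internal absent runs
    are all shorter than ``max_gap_frames``; an absent run of
    ``max_gap_frames`` or more (>= 20 s at 10-s frames) closes the event.
    Event start/end are the first/last present frame times.
    """
    if max_gap_frames < 1:
        raise ValueError("max_gap_frames must be >= 1")
    events: list[PerchingEvent] = []
    current: list[int] = []  # present-frame times of the open event
    gap = 0
    for t, present in frames.frames:
        if present:
            current.append(t)
            gap = 0
        else:
            gap += 1
            if gap >= max_gap_frames and current:
                events.append(_close(current, frames.frame_interval_s))
                current = []
    if current:
        events.append(_close(current, frames.frame_interval_s))
    return events


def _close(present_times: list[int], frame_interval_s: int) -> PerchingEvent:
    start, end = present_times[0], present_times[-1]
    return PerchingEvent(
        start_s=start,
        end_s=end,
        n_present_frames=len(present_times),
        duration_class=_duration_class(start, end),
    )


def _duration_class(start_s: int, end_s: int) -> str:
    return "gt20s" if (end_s - start_s) > 20 else "le20s"


def classify_event_duration(event: PerchingEvent, frame_interval_s: int = 10) -> str:
    """Duration class from the first-to-last-present span: > 20 s is ``gt20s``,
    otherwise ``le20s`` (a span of exactly 20 s falls in ``le20s``)."""
    return _duration_class(event.start_s, event.end_s)


def match_events(
    events: Sequence[PerchingEvent],
    dragonfly_images: Sequence[float],
    tolerance_s: float = 10,
    all_images: Sequence[float] | None = None,
) -> MatchResult:
    """Match trap images against perching events and compute sensitivity.

    An event is a true positive iff at least one dragonfly-image timestamp
    lies in [start - tolerance, end + tolerance]; otherwise a false
    negative.  Images (``all_images`` if given, else ``dragonfly_images``)
    are classified true_positive iff they fall inside some event's
    tolerance-padded span.  With no events at all the sensitivity is
    ``None`` (undefined; cf. a site where nothing ever perched).
    """
    ev_outcomes = []
    for ev in events:
        hit = any(
            ev.start_s - tolerance_s <= t <= ev.end_s + tolerance_s for t in dragonfly_images
        )
        ev_outcomes.append("true_positive" if hit else "false_negative")
    imgs = dragonfly_images if all_images is None else all_images
    img_outcomes = tuple(
        "true_positive"
        if any(ev.start_s - tolerance_s <= t <= ev.end_s + tolerance_s for ev in events)
        else "false_positive"
        for t in imgs
    )
    tp = ev_outcomes.count("true_positive")
    fn = ev_outcomes.count("false_negative")
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    return MatchResult(tuple(ev_outcomes), img_outcomes, tp, fn, sens)
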