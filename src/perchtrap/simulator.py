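"""Synthetic sky / perch / sensor simulator with ground-truth schedules.

Stands in for the physical trap so the detector and the validation pipeline
can be studied end to end at a desk.  The chain is:

    clear-sky irradiance (direct + diffuse, diurnal sine)
      -> stochastic cloud attenuation (mean-reverting, seeded)
      -> perch occlusion of the direct component at the top sensor
      -> photoresistor + ADC response (power-law CDS cell in a divider,
         Gaussian read noise, clamped and quantized to 0..1023)

All functional forms here are modelling plumbing — the trap's concept only
requires that a perching insect blocks direct sunlight at the top sensor
while the diffuser-fed reference sensor stays comparatively unchanged.
Defaults are chosen so that a midday perch occluding 10% of the direct
component moves the channel ratio by at least 5%, the Y = 1.05 operating
point of the detector.

Reproducibility: one top-level seed deterministically derives independent
sub-streams for clouds, the perch schedule, and the two channels' noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .detector import ADC_MAX, SensorSample, TriggerEvent

__all__ = [
    "SolarModel",
    "CloudModel",
    "PerchInterval",
    "SensorResponse",
    "clear_sky",
    "sample_cloud_path",
    "generate_perch_schedule",
    "simulate_trace",
    "simulate_camera",
]

DAY_S = 86_400


@dataclass(frozen=True)
class SolarModel:
    """Two-component clear-sky irradiance: direct beam + diffuse skylight.

    The direct component follows a half-sine between sunrise and sunset;
    the diffuse component is a fixed fraction of the direct plus a floor
    (night sky).  Units are arbitrary irradiance units; only ratios and the
    sensor transfer curve matter downstream.
    """

    sunrise_s: int = 6 * 3600
    sunset_s: int = 18 * 3600
    peak_direct: float = 1000.0
    diffuse_fraction: float = 0.15
    diffuse_floor: float = 20.0

    def __post_init__(self) -> None:
        if not self.sunrise_s < self.sunset_s:
            raise ValueError("sunrise_s must precede sunset_s")
        if self.peak_direct <= 0 or not (0 <= self.diffuse_fraction <= 1):
            raise ValueError("peak_direct > 0 and 0 <= diffuse_fraction <= 1 required")


@dataclass(frozen=True)
class CloudModel:
    """Mean-reverting stochastic cloud attenuation.

    A reflected Ornstein–Uhlenbeck optical-depth process x_t >= 0 is
    sampled at 1 Hz; the direct and diffuse components are attenuated by
    exp(-x * sensitivity).  ``volatility = 0`` gives a permanently clear
    sky (attenuation 1).  Clouds attenuate the direct beam more strongly
    than the diffuse skylight, which is exactly the asymmetry that can
    mimic a perch and drive false positives.
    """

    reversion_rate: float = 1.0 / 600.0
    volatility: float = 0.0
    direct_sensitivity: float = 1.0
    diffuse_sensitivity: float = 0.3

    def __post_init__(self) -> None:
        if self.reversion_rate < 0 or self.volatility < 0:
            raise ValueError("reversion_rate and volatility must be non-negative")
        if not (0 <= self.direct_sensitivity <= 1 and 0 <= self.diffuse_sensitivity <= 1):
            raise ValueError("sensitivities must lie in [0, 1]")


@dataclass(frozen=True)
class PerchInterval:
    """A ground-truth perching bout: [start_s, start_s + duration_s)."""

    start_s: float
    duration_s: float
    occlusion: float = 0.9

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if not (0 <= self.occlusion <= 1):
            raise ValueError("occlusion must lie in [0, 1]")

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    def contains_sample(self, time_s: int) -> bool:
        """Whether the sample stamped ``time_s`` (integrating (t-1, t]) is perched."""
        return self.start_s < time_s <= self.end_s


@dataclass(frozen=True)
class SensorResponse:
    """CDS photoresistor + voltage divider + 10-bit ADC transfer curve.

    The cell resistance falls with illuminance as a power law,
    R(E) = r0 * E^-gamma; the ADC reads the divider voltage across the
    cell, so darkness maps to high counts (the detector's ``dark_high``
    polarity).  ``half_scale_E = (r0 / r_fixed)^(1/gamma)`` is the
    illuminance at mid-scale; defaults put bright daylight in the lower
    half of the range and shade in the upper half.
    """

    gamma: float = 0.8
    r0: float = 1.0e6
    r_fixed: float = 1.05e4
    adc_max: int = ADC_MAX
    noise_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.gamma <= 0 or self.r0 <= 0 or self.r_fixed <= 0 or self.noise_sd < 0:
            raise ValueError("gamma, r0, r_fixed must be positive; noise_sd >= 0")

    def adc(self, illuminance: np.ndarray, rng: np.random.Generator | None = None) -> np.ndarray:
        """Map illuminance to integer ADC counts (vectorized, monotone decreasing)."""
        e = np.maximum(np.asarray(illuminance, dtype=float), 0.0)
        with np.errstate(divide="ignore"):
            resistance = np.where(e > 0, self.r0 * e ** (-self.gamma), np.inf)
        # divider fraction R/(R+Rf) written as 1/(1 + Rf/R) so R = inf -> 1 cleanly
        counts = self.adc_max / (1.0 + self.r_fixed / resistance)
        if rng is not None and self.noise_sd > 0:
            counts = counts + rng.normal(0.0, self.noise_sd, size=counts.shape)
        return np.clip(np.rint(counts), 0, self.adc_max).astype(np.int64)


def clear_sky(time_s: float, model: SolarModel) -> tuple[float, float]:
    """Clear-sky (direct, diffuse) irradiance at ``time_s`` (wraps over days)."""
    t = time_s % DAY_S
    span = model.sunset_s - model.sunrise_s
    if model.sunrise_s <= t <= model.sunset_s:
        direct = model.peak_direct * max(0.0, math.sin(math.pi * (t - model.sunrise_s) / span))
    else:
        direct = 0.0
    diffuse = model.diffuse_fraction * direct + model.diffuse_floor
    return direct, diffuse


def _clear_sky_arrays(times: np.ndarray, model: SolarModel) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float) % DAY_S
    span = model.sunset_s - model.sunrise_s
    up = (t >= model.sunrise_s) & (t <= model.sunset_s)
    direct = np.where(
        up,
        model.peak_direct * np.maximum(0.0, np.sin(np.pi * (t - model.sunrise_s) / span)),
        0.0,
    )
    return direct, model.diffuse_fraction * direct + model.diffuse_floor


def sample_cloud_path(duration_s: int, model: CloudModel, seed: int) -> np.ndarray:
    """Optical-depth path x_t >= 0 at 1 Hz, length ``duration_s``.

    Reflected OU process: x_{t+1} = |x_t (1 - k) + sigma * N(0,1)|, started
    at 0.  Identical seeds give bitwise-identical paths.  Attenuations are
    derived as exp(-x * sensitivity) by the caller.
    """
    if duration_s < 1:
        raise ValueError("duration_s must be >= 1")
    rng = np.random.default_rng(seed)
    if model.volatility == 0:
        return np.zeros(duration_s)
    shocks = rng.normal(0.0, model.volatility, size=duration_s)
    x = np.empty(duration_s)
    decay = max(0.0, 1.0 - model.reversion_rate)
    prev = 0.0
    for i in range(duration_s):
        prev = abs(prev * decay + shocks[i])
        x[i] = prev
    return x


def generate_perch_schedule(
    rate_per_h: float,
    duration_dist: Literal["exponential", "lognormal", "fixed"],
    duration_params: dict,
    window: tuple[float, float],
    seed: int,
    occlusion: float = 0.9,
    max_tries: int = 1000,
) -> list[PerchInterval]:
    """Poisson-process perch arrivals inside a daylight window.

    Arrival count ~ Poisson(rate * window_hours); starts uniform in the
    window; durations from the chosen distribution (``exponential``:
    ``mean_s``; ``lognormal``: ``mu``, ``sigma`` on log-seconds; ``fixed``:
    ``duration_s``).  Proposals that overlap an accepted interval or extend
    past the window end are rejected and resampled; output is sorted,
    non-overlapping, and wholly inside the window.

    Raises ``ValueError`` if the expected occupancy exceeds the window
    (infeasible density) or resampling cannot place all intervals.
    """
    if rate_per_h < 0:
        raise ValueError("rate_per_h must be >= 0")
    w0, w1 = window
    if w1 <= w0:
        raise ValueError("window must have positive length")
    rng = np.random.default_rng(seed)
    hours = (w1 - w0) / 3600.0
    mean_dur = _mean_duration(duration_dist, duration_params)
    expected_occupancy = rate_per_h * hours * mean_dur
    if expected_occupancy > (w1 - w0):
        raise ValueError(
            f"infeasible perch density: expected occupancy {expected_occupancy:.0f} s "
            f"exceeds window length {w1 - w0:.0f} s"
        )
    n = rng.poisson(rate_per_h * hours)
    placed: list[PerchInterval] = []
    for _ in range(n):
        for _try in range(max_tries):
            start = rng.uniform(w0, w1)
            dur = _draw_duration(duration_dist, duration_params, rng)
            if start + dur > w1:
                continue  # resample rather than truncate: keep durations as drawn
            cand = PerchInterval(start, dur, occlusion)
            if all(cand.end_s <= p.start_s or cand.start_s >= p.end_s for p in placed):
                placed.append(cand)
                break
        else:
            raise ValueError("could not place a non-overlapping perch interval")
    placed.sort(key=lambda p: p.start_s)
    return placed


def _mean_duration(dist: str, params: dict) -> float:
    if dist == "exponential":
        return float(params["mean_s"])
    if dist == "lognormal":
        return float(math.exp(params["mu"] + params["sigma"] ** 2 / 2))
    if dist == "fixed":
        return float(params["duration_s"])
    raise ValueError(f"unknown duration distribution {dist!r}")


def _draw_duration(dist: str, params: dict, rng: np.random.Generator) -> float:
    if dist == "exponential":
        return rng.exponential(params["mean_s"])
    if dist == "lognormal":
        return rng.lognormal(params["mu"], params["sigma"])
    return float(params["duration_s"])


def simulate_trace(
    solar: SolarModel,
    clouds: CloudModel,
    schedule: list[PerchInterval],
    response: SensorResponse,
    duration_s: int,
    seed: int,
    start_time_s: int = 0,
    direct_leakage: float = 0.0,
) -> tuple[list[SensorSample], list[PerchInterval]]:
    """Render a two-channel 1 Hz sensor trace plus its ground-truth echo.

    Per sample (stamped t = start+1 .. start+duration, integrating the
    preceding second):

        E1 = direct * cloud_direct * (1 - occlusion when perched) + diffuse * cloud_diffuse
        E2 = diffuse * cloud_diffuse + direct_leakage * direct * cloud_direct

    Both channels pass through the sensor response with independent noise
    streams.  ``direct_leakage`` models imperfect diffuser shading of the
    reference sensor (0 = ideal: sensor 2 is unaffected by perches).
    """
    ss = np.random.SeedSequence(seed)
    cloud_seed, noise1_seed, noise2_seed = [int(s) for s in ss.generate_state(3) % (2**31)]

    times = np.arange(start_time_s + 1, start_time_s + duration_s + 1)
    direct, diffuse = _clear_sky_arrays(times, solar)

    x = sample_cloud_path(duration_s, clouds, cloud_seed)
    att_direct = np.exp(-x * clouds.direct_sensitivity)
    att_diffuse = np.exp(-x * clouds.diffuse_sensitivity)

    occl = np.zeros(duration_s)
    for p in schedule:
        # samples with start < t <= end see the occlusion
        lo = int(np.searchsorted(times, math.floor(p.start_s) + 1))
        hi = int(np.searchsorted(times, math.floor(p.end_s), side="right"))
        occl[lo:hi] = np.maximum(occl[lo:hi], p.occlusion)

    beam = direct * att_direct
    sky = diffuse * att_diffuse
    e1 = beam * (1.0 - occl) + sky
    e2 = sky + direct_leakage * beam

    s1 = response.adc(e1, np.random.default_rng(noise1_seed))
    s2 = response.adc(e2, np.random.default_rng(noise2_seed))

    trace = [
        SensorSample(int(t), int(a), int(b)) for t, a, b in zip(times, s1, s2)
    ]
    return trace, list(schedule)


def simulate_camera(
    triggers: list[TriggerEvent],
    truth: list[PerchInterval],
    sleep_after_s: int = 60,
) -> list[tuple[int, bool]]:
    """Model the sleeping camera's response to reboot/shutter commands.

    The trap cannot query the camera, so the reboot pulse doubles as a
    shutter press whenever the camera happens to be awake (awake = within
    ``sleep_after_s`` of its last activity).  A shutter command always
    takes a photo.  Returns an image log of (time_s, dragonfly_present)
    where presence means the timestamp falls inside a ground-truth perch.
    """
    images: list[tuple[int, bool]] = []
    last_activity: float = -math.inf
    for trig in sorted(triggers, key=lambda e: e.time_s):
        awake = (trig.time_s - last_activity) <= sleep_after_s
        if trig.kind == "shutter" or (trig.kind == "reboot" and awake):
            present = any(p.contains_sample(trig.time_s) for p in truth)
            images.append((trig.time_s, present))
        last_activity = trig.time_s
    return images
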