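"""Synthetic multichannel regional recordings with annotated spikes.

Emulates resting-state gradiometer data from one brain region: 26 (or 24)
channels at 1000 Hz of band-limited (1-50 Hz) Gaussian background at unit
RMS per channel, into which sharp biphasic transients ("interictal
spikes") are inserted coherently across all channels of the region, with
per-channel gain jitter standing in for the spatial falloff of the
magnetic field across the sensor patch.

Spike timing is a Poisson process thinned to keep events non-overlapping;
spike durations follow a truncated normal (mean 70 ms, sd 25 ms, bounds
20-150 ms).  Amplitude is controlled by ``snr``, the ratio of the spike's
peak amplitude to the background RMS.  The generator is fully
deterministic under a fixed seed, which makes every downstream stage
testable without clinical data; what it does *not* model (1/f spectra,
ocular/cardiac artifacts, nonstationarity) is discussed in the methods
note.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps
from scipy import stats

from .preprocess import Recording


class PlacementError(RuntimeError):
    """Spike rate too high to place non-overlapping events."""


@dataclass
class SimulationConfig:
    fs: float = 1000.0
    duration_s: float = 60.0
    n_channels: int = 26
    region: str = "left_temporal"
    spike_rate: float = 10.0          # events per minute
    duration_mean_ms: float = 70.0
    duration_sd_ms: float = 25.0
    duration_bounds_ms: tuple[float, float] = (20.0, 150.0)
    snr: float = 5.0                  # spike peak / background RMS
    channel_attenuation_sd: float = 0.2
    background_band: tuple[float, float] = (1.0, 50.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.spike_rate < 0:
            raise ValueError("spike_rate must be >= 0")
        lo, hi = self.duration_bounds_ms
        if not 0 < lo < hi:
            raise ValueError("duration bounds must be positive and ordered")
        if self.n_channels not in (24, 26):
            raise ValueError("n_channels must be 24 or 26")


@dataclass
class AnnotatedRecording:
    recording: Recording
    events: list[tuple[int, int]] = field(default_factory=list)


def make_background(cfg: SimulationConfig,
                    rng: np.random.Generator) -> Recording:
    """Independent band-limited Gaussian noise, unit RMS per channel."""
    n = int(round(cfg.duration_s * cfg.fs))
    raw = rng.standard_normal((cfg.n_channels, n))
    nyq = cfg.fs / 2.0
    lo, hi = cfg.background_band
    sos = sps.butter(4, [lo / nyq, hi / nyq], btype="bandpass", output="sos")
    filtered = sps.sosfiltfilt(sos, raw, axis=1)
    rms = np.sqrt(np.mean(filtered ** 2, axis=1, keepdims=True))
    return Recording(data=filtered / rms, fs=cfg.fs, region=cfg.region)


def spike_template(duration_samples: int,
                   rng: np.random.Generator | None = None) -> np.ndarray:
    """Biphasic sharp transient of the given length.

    A Mexican-hat (second derivative of a Gaussian) waveform: zero mean,
    peak amplitude normalized to 1.  The shape itself is deterministic;
    per-event variability enters through duration and channel gains.
    """
    if duration_samples < 10:
        raise ValueError("spike duration must be >= 10 samples")
    t = np.linspace(-1.0, 1.0, duration_samples)
    a = 0.2  # main-lobe width relative to half-duration: sharp transient
    w = (1.0 - (t / a) ** 2) * np.exp(-(t ** 2) / (2 * a ** 2))
    w = w - w.mean()
    return w / np.max(np.abs(w))


def _draw_durations(cfg: SimulationConfig, rng: np.random.Generator,
                    n: int) -> np.ndarray:
    lo, hi = cfg.duration_bounds_ms
    a = (lo - cfg.duration_mean_ms) / cfg.duration_sd_ms
    b = (hi - cfg.duration_mean_ms) / cfg.duration_sd_ms
    ms = stats.truncnorm.rvs(a, b, loc=cfg.duration_mean_ms,
                             scale=cfg.duration_sd_ms, size=n,
                             random_state=rng)
    return np.maximum((ms * cfg.fs / 1000.0).round().astype(int), 10)


def _place_events(durations: np.ndarray, n_samples: int,
                  rng: np.random.Generator,
                  max_tries: int = 1000) -> list[tuple[int, int]]:
    """Uniform non-overlapping placement with bounded rejection retries."""
    events: list[tuple[int, int]] = []
    for dur in durations:
        if dur >= n_samples:
            raise PlacementError("event longer than the recording")
        for _ in range(max_tries):
            start = int(rng.integers(0, n_samples - dur))
            if all(start + dur <= s or start >= e for s, e in events):
                events.append((start, start + dur))
                break
        else:
            raise PlacementError(
                "could not place non-overlapping events; lower spike_rate")
    return sorted(events)


def simulate(cfg: SimulationConfig) -> AnnotatedRecording:
    """Background plus Poisson-placed coherent regional spikes.

    Each event's template, scaled by ``snr`` and per-channel gains drawn
    from Normal(1, channel_attenuation_sd) truncated positive, is added to
    all channels simultaneously.  Events are recorded as half-open
    [start, end) sample intervals.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    recording = make_background(cfg, rng)
    n_events = rng.poisson(cfg.spike_rate * cfg.duration_s / 60.0)
    durations = _draw_durations(cfg, rng, n_events)
    events = _place_events(durations, recording.n_samples, rng)
    for start, end in events:
        template = spike_template(end - start, rng)
        gains = rng.normal(1.0, cfg.channel_attenuation_sd,
                           size=cfg.n_channels)
        gains = np.abs(gains)
        gains[gains < 0.05] = 0.05  # keep every channel's gain positive
        recording.data[:, start:end] += (
            cfg.snr * gains[:, None] * template[None, :])
    return AnnotatedRecording(recording=recording, events=events)
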