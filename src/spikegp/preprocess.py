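"""Segmentation, smoothing and statistical feature extraction.

Each channel of a multichannel recording is cut into fixed-length
overlapping windows (100 ms, 50% overlap at the defaults), each window is
median-smoothed, and eight order/moment statistics are computed per window:

    X1 = max        X2 = min       X3 = mean       X4 = standard deviation
    X5 = median     X6 = IQR       X7 = kurtosis   X8 = skewness

The dispersion and shape statistics deliberately use 1/(N-1) normalizations
throughout — sigma^2 = sum((x-mu)^2)/(N-1), kurtosis =
sum((x-mu)^4)/((N-1) sigma^4), skewness = sum((x-mu)^3)/((N-1) sigma^3) —
rather than the 1/N population forms or bias-corrected estimators.  The IQR
uses exclusive-halves quartiles: Q1/Q3 are the medians of the lower/upper
halves of the sorted window, the overall median being excluded from both
halves when N is odd.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter

FEATURE_NAMES = ("X1", "X2", "X3", "X4", "X5", "X6", "X7", "X8")

#: labels carried by segments / windows
SPIKE, NONSPIKE, UNKNOWN = 1, 0, -1

VALID_CHANNEL_COUNTS = (24, 26)

REGION_NAMES = (
    "left_frontal", "right_frontal",
    "left_temporal", "right_temporal",
    "left_parietal", "right_parietal",
    "left_occipital", "right_occipital",
)


class EmptyInputError(ValueError):
    """Signal shorter than one analysis window."""


class AnnotationError(ValueError):
    """Malformed spike annotation interval."""


@dataclass(frozen=True)
class SegmentationConfig:
    """Windowing parameters.

    window_ms : window duration in milliseconds (100 ms default, chosen to
        cover the bulk of interictal spike durations).
    overlap_fraction : fraction of the window shared by consecutive
        windows (0.5 default).
    median_filter_order : odd kernel length of the per-window median
        smoother (5 default).
    """

    window_ms: float = 100.0
    overlap_fraction: float = 0.5
    median_filter_order: int = 5

    def __post_init__(self) -> None:
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")
        if not 0 <= self.overlap_fraction < 1:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.median_filter_order < 1 or self.median_filter_order % 2 == 0:
            raise ValueError("median_filter_order must be odd and >= 1")

    def window_samples(self, fs: float) -> int:
        """Window length N in samples; exactly 100 at fs=1000 Hz."""
        return int(round(self.window_ms * fs / 1000.0))

    def step_samples(self, fs: float) -> int:
        n = self.window_samples(fs)
        step = int(round(n * (1.0 - self.overlap_fraction)))
        return max(step, 1)


@dataclass
class Recording:
    """A channels x samples field-amplitude matrix with its sampling rate.

    One recording holds all channels of a single brain region (26, or 24
    for the occipital regions).
    """

    data: np.ndarray
    fs: float
    region: str = "left_temporal"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D channels x samples matrix")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.data.shape[0] not in VALID_CHANNEL_COUNTS:
            raise ValueError(
                f"channel count must be one of {VALID_CHANNEL_COUNTS}, "
                f"got {self.data.shape[0]}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def channel_count(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs


@dataclass
class Segment:
    """One channel's window of N consecutive samples."""

    values: np.ndarray
    channel_index: int = 0
    start_sample: int = 0
    label: int = UNKNOWN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.start_sample < 0:
            raise ValueError("start_sample must be >= 0")


def window_starts(n_samples: int, window: int, step: int) -> np.ndarray:
    """0-based start indices of full windows; trailing partial discarded."""
    if n_samples < window:
        raise EmptyInputError(
            f"signal of {n_samples} samples shorter than window of {window}"
        )
    n_windows = (n_samples - window) // step + 1
    return np.arange(n_windows) * step


def segment_channel(
    signal: np.ndarray, cfg: SegmentationConfig, fs: float,
    channel_index: int = 0,
) -> list[Segment]:
    """Cut one channel into overlapping windows.

    Returns floor((L-N)/step)+1 segments; any trailing samples not filling
    a whole window are dropped.
    """
    signal = np.asarray(signal, dtype=float)
    n = cfg.window_samples(fs)
    step = cfg.step_samples(fs)
    starts = window_starts(signal.size, n, step)
    return [
        Segment(values=signal[s:s + n], channel_index=channel_index,
                start_sample=int(s))
        for s in starts
    ]


def median_smooth(values: np.ndarray, order: int) -> np.ndarray:
    """Sliding-window median with edge replication; order 1 is identity."""
    if order % 2 == 0 or order < 1:
        raise ValueError("median filter order must be odd and >= 1")
    values = np.asarray(values, dtype=float)
    if order == 1:
        return values.copy()
    if order > values.shape[-1]:
        raise ValueError("median filter order exceeds segment length")
    # mode="nearest" replicates the edge sample into the out-of-range taps
    return median_filter(values, size=(1,) * (values.ndim - 1) + (order,),
                         mode="nearest")


def _half_medians(sorted_rows: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Q1/Q3 as medians of the exclusive lower/upper halves (rows sorted)."""
    n = sorted_rows.shape[-1]
    lower = sorted_rows[..., : n // 2]
    upper = sorted_rows[..., (n + 1) // 2:]
    return np.median(lower, axis=-1), np.median(upper, axis=-1)


def features_matrix(windows: np.ndarray) -> np.ndarray:
    """Eight statistics for each row of a (n_windows, N) matrix.

    Vectorized core shared by `extract_features` and the detection stage.
    Zero-variance rows get kurtosis = skewness = 0 so downstream formula
    evaluation never sees non-finite values.
    """
    w = np.atleast_2d(np.asarray(windows, dtype=float))
    n = w.shape[1]
    if n < 2:
        raise ValueError("windows must contain at least 2 samples")
    mu = w.mean(axis=1)
    dev = w - mu[:, None]
    var = (dev ** 2).sum(axis=1) / (n - 1)
    sigma = np.sqrt(var)
    s = np.sort(w, axis=1)
    q1, q3 = _half_medians(s)
    with np.errstate(divide="ignore", invalid="ignore"):
        kurt = (dev ** 4).sum(axis=1) / ((n - 1) * sigma ** 4)
        skew = (dev ** 3).sum(axis=1) / ((n - 1) * sigma ** 3)
    degenerate = sigma == 0
    kurt[degenerate] = 0.0
    skew[degenerate] = 0.0
    out = np.column_stack([
        w.max(axis=1), w.min(axis=1), mu, sigma,
        np.median(w, axis=1), q3 - q1, kurt, skew,
    ])
    return out


def extract_features(segment: Segment | np.ndarray) -> np.ndarray:
    """FeatureVector (X1..X8) of a single segment."""
    values = segment.values if isinstance(segment, Segment) else segment
    return features_matrix(np.asarray(values, dtype=float)[None, :])[0]


def label_segment(
    start_sample: int, window: int,
    annotations: Sequence[tuple[int, int]],
) -> int:
    """Spike iff the window overlaps an annotated interval by >= half the
    window length.  Intervals are half-open [start, end) in 0-based samples.
    """
    w0, w1 = start_sample, start_sample + window
    threshold = window / 2.0
    for a0, a1 in annotations:
        if a1 <= a0:
            raise AnnotationError(f"malformed interval [{a0}, {a1})")
        overlap = min(w1, a1) - max(w0, a0)
        if overlap >= threshold:
            return SPIKE
    return NONSPIKE


def sliding_windows(signal: np.ndarray, window: int, step: int) -> np.ndarray:
    """All full windows of a 1-D signal as a (n_windows, window) view-copy."""
    starts = window_starts(np.asarray(signal).shape[-1], window, step)
    sw = np.lib.stride_tricks.sliding_window_view(signal, window, axis=-1)
    return sw[..., starts, :]


def channel_features(
    signal: np.ndarray, cfg: SegmentationConfig, fs: float,
) -> tuple[np.ndarray, np.ndarray]:
    """(starts, features) for one channel: segment, smooth, extract.

    Returns the 0-based window start samples and the (n_windows, 8) feature
    matrix, computed on median-smoothed windows.
    """
    n = cfg.window_samples(fs)
    step = cfg.step_samples(fs)
    wins = sliding_windows(np.asarray(signal, dtype=float), n, step)
    smoothed = median_smooth(wins, cfg.median_filter_order)
    return window_starts(np.asarray(signal).shape[-1], n, step), \
        features_matrix(smoothed)


def recording_features(
    recording: Recording, cfg: SegmentationConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """(starts, features) for a whole recording.

    features has shape (channels, n_windows, 8).
    """
    n = cfg.window_samples(recording.fs)
    step = cfg.step_samples(recording.fs)
    starts = window_starts(recording.n_samples, n, step)
    wins = sliding_windows(recording.data, n, step)  # (C, W, N)
    c, w_count, _ = wins.shape
    smoothed = median_smooth(wins.reshape(c * w_count, n),
                             cfg.median_filter_order)
    feats = features_matrix(smoothed).reshape(c, w_count, len(FEATURE_NAMES))
    return starts, feats


# ---------------------------------------------------------------------------
# text I/O: recording CSV/TSV with "# fs=<Hz> region=<name>" header,
# annotation TSV, feature-table TSV
# ---------------------------------------------------------------------------

def write_recording(path, recording: Recording, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# fs={recording.fs:g} region={recording.region}\n")
        np.savetxt(fh, recording.data, delimiter=sep, fmt="%.6g")


def read_recording(path) -> Recording:
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing '# fs=<Hz> region=<name>' header line")
        meta = dict(
            item.split("=", 1) for item in header.lstrip("# ").split()
        )
        body = fh.read()
    sep = "\t" if "\t" in body.splitlines()[0] else ","
    data = np.loadtxt(io.StringIO(body), delimiter=sep, ndmin=2)
    return Recording(data=data, fs=float(meta["fs"]),
                     region=meta.get("region", "left_temporal"))


def write_annotations(path, events: Sequence[tuple[int, int]],
                      region: str = "left_temporal") -> None:
    df = pd.DataFrame(events, columns=["start_sample", "end_sample"])
    df["region"] = region
    df.to_csv(path, sep="\t", index=False)


def read_annotations(path) -> list[tuple[int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [(int(r.start_sample), int(r.end_sample))
            for r in df.itertuples()]


def feature_table(
    recording: Recording, cfg: SegmentationConfig,
    annotations: Sequence[tuple[int, int]] | None = None,
) -> pd.DataFrame:
    """Long-format per-segment feature table with labels.

    Columns: channel, start_sample, X1..X8, label.  Labels come from
    `label_segment` when annotations are given, else UNKNOWN.
    """
    starts, feats = recording_features(recording, cfg)
    n = cfg.window_samples(recording.fs)
    if annotations is not None:
        labels = np.array(
            [label_segment(int(s), n, annotations) for s in starts]
        )
    else:
        labels = np.full(starts.size, UNKNOWN)
    frames = []
    for ch in range(recording.channel_count):
        df = pd.DataFrame(feats[ch], columns=list(FEATURE_NAMES))
        df.insert(0, "start_sample", starts)
        df.insert(0, "channel", ch)
        df["label"] = labels
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
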