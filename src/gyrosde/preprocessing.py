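"""Raw recordings -> normalized 4-channel windowed sequences.

Pipeline order is fixed: magnitude feature first (on raw rad/s values),
then z-scoring of all four channels with statistics fit on the training
split only, then windowing. Windows carry T+1 frames so that T transitions
and T midpoint targets are defined within a single window.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateDataError, InvalidArgumentError
from .synthetic import SensorRecording


def compute_magnitude(omega) -> np.ndarray:
    """Euclidean norm of the three angular-velocity axes.

    Accepts a single 3-vector or an (N, 3) array; returns a scalar or
    (N,) array of the same kind.
    """
    omega = np.asarray(omega, dtype=float)
    if omega.shape[-1] != 3:
        raise InvalidArgumentError("omega must have 3 components on last axis")
    if not np.all(np.isfinite(omega)):
        raise InvalidArgumentError("omega contains non-finite values")
    out = np.sqrt(np.sum(omega * omega, axis=-1))
    return float(out) if out.ndim == 0 else out


def recording_to_frames(recording: SensorRecording) -> np.ndarray:
    """Stack (omega_x, omega_y, omega_z, omega_T) into raw (N, 4) frames."""
    mag = compute_magnitude(recording.omega)
    return np.column_stack([recording.omega, mag])


@dataclass
class NormalizationStats:
    """Per-channel z-score statistics (population sd), fit on train only."""

    mean: np.ndarray
    sd: np.ndarray

    def __post_init__(self):
        self.mean = np.asarray(self.mean, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if np.any(self.sd <= 0):
            raise DegenerateDataError("standard deviations must be positive")


def fit_zscore(train_frames: np.ndarray) -> NormalizationStats:
    """Fit per-channel mean and population standard deviation."""
    frames = np.asarray(train_frames, dtype=float)
    if frames.ndim != 2 or frames.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 frames to fit z-scores")
    mean = frames.mean(axis=0)
    sd = frames.std(axis=0)  # population (ddof=0)
    if np.any(sd <= 1e-12):
        bad = np.nonzero(sd <= 1e-12)[0].tolist()
        raise DegenerateDataError(f"zero-variance channel(s) {bad}")
    return NormalizationStats(mean=mean, sd=sd)


def apply_zscore(frames: np.ndarray, stats: NormalizationStats) -> np.ndarray:
    return (np.asarray(frames, dtype=float) - stats.mean) / stats.sd


def split_train_test(frames: np.ndarray, train_fraction: float = 0.8):
    """Chronological split: first floor(f*N) samples are training."""
    frames = np.asarray(frames)
    n = len(frames)
    if n < 2:
        raise InvalidArgumentError("sequence too short to split")
    if not (0.0 < train_fraction <= 1.0):
        raise InvalidArgumentError("train_fraction must be in (0, 1]")
    n_train = int(np.floor(train_fraction * n))
    if n_train == n:
        warnings.warn("train_fraction leaves an empty test split",
                      stacklevel=2)
    return frames[:n_train], frames[n_train:]


@dataclass
class WindowedDataset:
    """Fixed-length windows of (T+1) x 4 normalized frames.

    ``windows`` has shape (n_windows, T+1, 4); ``starts`` records the
    0-based start index of each half-open window [start, start+T+1).
    """

    windows: np.ndarray
    T: int
    stride: int
    starts: np.ndarray = field(default=None)

    def __post_init__(self):
        self.windows = np.asarray(self.windows, dtype=float)
        if self.windows.ndim != 3 or self.windows.shape[1] != self.T + 1:
            raise InvalidArgumentError(
                f"windows must be (n, {self.T + 1}, d); got {self.windows.shape}"
            )

    def __len__(self) -> int:
        return len(self.windows)


def make_windows(frames: np.ndarray, T: int = 90,
                 stride: int | None = None) -> WindowedDataset:
    """Slice frames into windows of T+1 frames; trailing partial dropped.

    stride defaults to T (non-overlapping training windows); stride=1
    gives the dense windows used for trajectory extraction.
    """
    frames = np.asarray(frames, dtype=float)
    if stride is None:
        stride = T
    if T < 1 or stride < 1:
        raise InvalidArgumentError("T and stride must be >= 1")
    n = len(frames)
    if n < T + 1:
        raise InvalidArgumentError(f"need at least {T + 1} frames, got {n}")
    count = (n - (T + 1)) // stride + 1
    starts = np.arange(count) * stride
    windows = np.stack([frames[s:s + T + 1] for s in starts])
    return WindowedDataset(windows=windows, T=T, stride=stride, starts=starts)


def midpoint_targets(window: np.ndarray) -> np.ndarray:
    """Midpoints (x_t + x_{t+1}) / 2: the decoder's reconstruction/
    prediction compromise. A window of L frames yields L-1 targets."""
    window = np.asarray(window, dtype=float)
    if len(window) < 2:
        raise InvalidArgumentError("window must contain at least 2 frames")
    return 0.5 * (window[:-1] + window[1:])


def prepare_recordings(recordings: list[SensorRecording], T: int = 90,
                       stride: int | None = None,
                       train_fraction: float = 0.8):
    """Full pipeline over one or more recordings.

    Each recording is split chronologically; z-score statistics are fit on
    the pooled training segments of all recordings (multi-motion runs pool
    their data into one normalization), then both segments are normalized
    and windowed.

    Returns ``(train_ds, test_ds, stats, train_ids, test_ids)`` where the
    id arrays give the source-recording index of every window.
    """
    if not recordings:
        raise InvalidArgumentError("no recordings given")
    raw = [recording_to_frames(r) for r in recordings]
    splits = [split_train_test(f, train_fraction) for f in raw]
    stats = fit_zscore(np.concatenate([tr for tr, _ in splits]))

    def _collect(segments):
        win_list, ids = [], []
        for idx, seg in enumerate(segments):
            if len(seg) < T + 1:
                continue
            ds = make_windows(apply_zscore(seg, stats), T=T, stride=stride)
            win_list.append(ds.windows)
            ids.extend([idx] * len(ds))
        if not win_list:
            raise InvalidArgumentError(
                f"no segment long enough for a {T + 1}-frame window"
            )
        windows = np.concatenate(win_list)
        return (WindowedDataset(windows=windows, T=T, stride=stride or T),
                np.asarray(ids))

    train_ds, train_ids = _collect([tr for tr, _ in splits])
    test_segments = [te for _, te in splits]
    try:
        test_ds, test_ids = _collect(test_segments)
    except InvalidArgumentError:
        test_ds, test_ids = None, np.asarray([], dtype=int)
    return train_ds, test_ds, stats, train_ids, test_ids
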