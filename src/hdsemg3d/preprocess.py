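"""Signal conditioning and muscle-activity segmentation.

The conditioning chain mirrors standard HD-sEMG practice for raw bipolar
recordings: a zero-lag (forward-backward) fourth-order Butterworth band-pass
at 20-400 Hz removes motion artifact and out-of-band noise without phase
distortion; full-wave rectification followed by a zero-lag 4 Hz low-pass
yields the *intensity envelope*, a slow nonnegative trace of activation
level per channel.  Muscle activity is then located by thresholding the
envelope on non-overlapping windows of 150 samples: the per-window,
all-channel mean intensity is summed, the threshold is the mean of those
window sums, and the longest contiguous supra-threshold run is returned, so
the detected segment length is always a multiple of the window length.

Pre-segmented data already normalized to [-1, 1] (CapgMyo-style) bypasses
this chain and only needs :func:`normalize_unit_interval`.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.signal import butter, filtfilt

__all__ = [
    "IntensityEnvelope",
    "ActivitySegment",
    "NoActivityError",
    "normalize_unit_interval",
    "bandpass_zero_lag",
    "intensity_envelope",
    "segment_activity",
    "export_segments",
]


class NoActivityError(RuntimeError):
    """No window's summed intensity exceeded the segmentation threshold."""


@dataclass
class IntensityEnvelope:
    """Nonnegative channels x frames activation-level trace."""

    values: np.ndarray
    fs: float
    cutoff: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("envelope must be channels x frames")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be nonnegative")


@dataclass(frozen=True)
class ActivitySegment:
    """Half-open frame interval of detected activity, window-aligned."""

    start_frame: int
    end_frame: int
    window_len: int

    def __post_init__(self) -> None:
        n = self.end_frame - self.start_frame
        if n <= 0 or n % self.window_len:
            raise ValueError(
                "segment length must be a positive multiple of window_len"
            )

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


def normalize_unit_interval(
    signal: np.ndarray, source_range: tuple[float, float]
) -> np.ndarray:
    """Affine map of ``[lo, hi]`` onto [0, 1], clipping values outside."""
    lo, hi = source_range
    if not hi > lo:
        raise ValueError(f"degenerate source range ({lo}, {hi})")
    out = (np.asarray(signal, dtype=np.float64) - lo) / (hi - lo)
    return np.clip(out, 0.0, 1.0)


def _zero_lag(signal: np.ndarray, b: np.ndarray, a: np.ndarray, order: int) -> np.ndarray:
    # reflective padding of 3*order samples suppresses edge transients
    return filtfilt(b, a, np.asarray(signal, dtype=np.float64), axis=-1,
                    padtype="even", padlen=3 * order)


def bandpass_zero_lag(
    signal: np.ndarray,
    fs: float,
    low: float = 20.0,
    high: float = 400.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth band-pass, applied per channel.

    Forward-backward filtering cancels the filter's phase response, so burst
    onsets are not delayed -- essential when the filtered trace feeds
    activity segmentation.
    """
    nyq = fs / 2.0
    if not 0 < low < high:
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cutoff {high} Hz >= Nyquist {nyq} Hz")
    b, a = butter(order, [low / nyq, high / nyq], btype="bandpass")
    return _zero_lag(signal, b, a, order)


def intensity_envelope(
    signal: np.ndarray,
    fs: float,
    cutoff: float = 4.0,
    order: int = 4,
) -> IntensityEnvelope:
    """Full-wave rectification followed by a zero-lag low-pass.

    Tiny negative excursions from filter ringing are clamped to zero so the
    envelope is a valid nonnegative intensity.
    """
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise ValueError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    rectified = np.abs(np.asarray(signal, dtype=np.float64))
    b, a = butter(order, cutoff / nyq, btype="lowpass")
    smoothed = _zero_lag(rectified, b, a, order)
    return IntensityEnvelope(np.maximum(smoothed, 0.0), fs=fs, cutoff=cutoff)


def segment_activity(
    env: IntensityEnvelope, window_len: int = 150
) -> ActivitySegment:
    """Locate the dominant activity burst by windowed thresholding.

    Non-overlapping windows of ``window_len`` frames (a trailing partial
    window is discarded); per window the channel-mean intensities are summed
    over channels, the threshold is the mean of the window sums, and windows
    strictly above threshold are active.  The longest contiguous active run
    is returned as a frame interval (ties go to the earliest run).  One
    gesture per trial implies a single dominant burst, hence "longest run"
    rather than all runs.
    """
    values = env.values
    n_frames = values.shape[1]
    n_windows = n_frames // window_len
    if n_windows < 1:
        raise ValueError(
            f"need at least {window_len} frames, got {n_frames}"
        )
    trimmed = values[:, : n_windows * window_len]
    # a(w, c): mean intensity of channel c in window w; S(w) = sum_c a(w, c)
    per_window = trimmed.reshape(values.shape[0], n_windows, window_len).mean(axis=2)
    window_sums = per_window.sum(axis=0)
    threshold = window_sums.mean()
    active = window_sums > threshold
    if not active.any():
        raise NoActivityError("no activity detected")

    best_start = best_len = 0
    run_start = None
    for w, flag in enumerate(list(active) + [False]):
        if flag and run_start is None:
            run_start = w
        elif not flag and run_start is not None:
            if w - run_start > best_len:
                best_start, best_len = run_start, w - run_start
            run_start = None
    return ActivitySegment(
        start_frame=best_start * window_len,
        end_frame=(best_start + best_len) * window_len,
        window_len=window_len,
    )


def export_segments(
    segments: dict[str, ActivitySegment], path: str | Path
) -> Path:
    """Write segments as a 3-column TSV (trial-id, start, end), half-open."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("trial_id\tstart_frame\tend_frame\n")
        for trial_id, seg in segments.items():
            f.write(f"{trial_id}\t{seg.start_frame}\t{seg.end_frame}\n")
    return path
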