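"""Instantaneous-image sequences and spatiotemporal training cubes.

A normalized recording becomes an :class:`ImageSequence` (one ``h x w``
image per frame); sliding windows of ``l`` consecutive images stacked along
time form ``l x h x w x 1`` *cubes*, the classifier's input unit.  Training
protocols may use an overlapping stride (e.g. stride 2) as data
augmentation; test-time extraction is non-overlapping (stride = l) so that
voting-window bookkeeping in milliseconds is exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid_io import Recording, frames_to_images
from .preprocess import ActivitySegment

__all__ = [
    "ImageSequence",
    "CubeDataset",
    "build_image_sequence",
    "extract_cubes",
    "window_frames",
    "split_trials",
    "save_cubes",
    "load_cubes",
]


@dataclass
class ImageSequence:
    """``l_total x h x w`` stack of [0, 1] images with one gesture label."""

    frames: np.ndarray
    fs: float
    label: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be l_total x h x w")
        if self.frames.min() < 0 or self.frames.max() > 1:
            raise ValueError("image values must lie in [0, 1]; normalize first")

    def __len__(self) -> int:
        return self.frames.shape[0]


@dataclass
class CubeDataset:
    """Labeled ``n x l x h x w x 1`` cube array ready for training."""

    cubes: np.ndarray
    labels: np.ndarray
    l: int
    stride: int
    origin: str = ""

    def __post_init__(self) -> None:
        self.cubes = np.asarray(self.cubes)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.cubes.ndim != 5 or self.cubes.shape[4] != 1:
            raise ValueError("cubes must be n x l x h x w x 1")
        if self.cubes.shape[0] != self.labels.shape[0]:
            raise ValueError("cube/label count mismatch")

    def __len__(self) -> int:
        return self.cubes.shape[0]

    @staticmethod
    def concatenate(parts: list["CubeDataset"]) -> "CubeDataset":
        if not parts:
            raise ValueError("nothing to concatenate")
        return CubeDataset(
            cubes=np.concatenate([p.cubes for p in parts]),
            labels=np.concatenate([p.labels for p in parts]),
            l=parts[0].l,
            stride=parts[0].stride,
            origin=parts[0].origin,
        )


def build_image_sequence(
    rec: Recording, segment: ActivitySegment | None = None
) -> ImageSequence:
    """One image per frame of the segment (or the whole trial).

    The recording must already be normalized to [0, 1].
    """
    if rec.signal.min() < 0 or rec.signal.max() > 1:
        raise ValueError("recording not normalized to [0, 1]")
    start, end = (0, rec.n_frames) if segment is None else (
        segment.start_frame, segment.end_frame)
    frames = frames_to_images(rec, start, end)
    meta = dict(rec.meta)
    meta["segment"] = (start, end)
    return ImageSequence(frames=frames, fs=rec.fs,
                         label=int(rec.meta.get("gesture", -1)), meta=meta)


def extract_cubes(seq: ImageSequence, l: int, stride: int) -> CubeDataset:
    """Sliding-window cube extraction.

    Windows start at frame 0, ``stride`` apart, with the last window fully
    inside the sequence: ``count = (len - l) // stride + 1``.
    """
    if l < 1 or stride < 1:
        raise ValueError("l and stride must be >= 1")
    n_total = len(seq)
    if n_total < l:
        raise ValueError(f"sequence length {n_total} shorter than cube l={l}")
    n = (n_total - l) // stride + 1
    sw = np.lib.stride_tricks.sliding_window_view(seq.frames, l, axis=0)
    # sw: (n_total - l + 1, h, w, l) -> pick strided starts, reorder to l,h,w
    cubes = np.ascontiguousarray(
        np.moveaxis(sw[::stride][:n], -1, 1)[..., np.newaxis]
    )
    labels = np.full(n, seq.label, dtype=np.int64)
    return CubeDataset(cubes=cubes, labels=labels, l=l, stride=stride)


def window_frames(duration_ms: float, fs: float) -> int:
    """Convert a window duration in ms to frames: ``floor(ms * fs / 1000)``."""
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    return int(np.floor(duration_ms * fs / 1000.0))


def split_trials(
    trials: list, scheme: str, k: int | None = None
) -> tuple[list, list]:
    """Deterministic train/test partition of a trial list.

    ``half-half-by-trial``: even-indexed trials train, odd-indexed test
    (the conventional alternating split when the source does not specify
    which half is which).  ``leave-one-trial-out``: trial ``k`` tests, the
    rest train.
    """
    if scheme == "half-half-by-trial":
        train = [t for i, t in enumerate(trials) if i % 2 == 0]
        test = [t for i, t in enumerate(trials) if i % 2 == 1]
        return train, test
    if scheme == "leave-one-trial-out":
        if k is None or not 0 <= k < len(trials):
            raise ValueError(f"leave-one-out fold k={k} out of range")
        return [t for i, t in enumerate(trials) if i != k], [trials[k]]
    raise ValueError(f"unknown split scheme {scheme!r}")


def save_cubes(ds: CubeDataset, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("cubes", data=ds.cubes)
        f.create_dataset("labels", data=ds.labels)
        f.attrs["l"] = ds.l
        f.attrs["stride"] = ds.stride
        f.attrs["origin"] = ds.origin


def load_cubes(path) -> CubeDataset:
    import h5py

    with h5py.File(path, "r") as f:
        return CubeDataset(
            cubes=f["cubes"][()],
            labels=f["labels"][()],
            l=int(f.attrs["l"]),
            stride=int(f.attrs["stride"]),
            origin=str(f.attrs.get("origin", "")),
        )
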