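"""Electrode-grid data model and container I/O for HD-sEMG recordings.

A high-density surface EMG recording is a ``channels x frames`` matrix tied
to a 2D electrode grid.  :class:`ElectrodeGrid` holds the geometry and the
bijection from channel index to ``(row, col)`` pixel; :class:`Recording`
bundles the signal with its sampling rate and provenance metadata.  A single
time frame rearranged by electrode geometry is an *instantaneous sEMG image*
(:func:`frame_to_image`).

Supported containers: HDF5 (native), NPY with a JSON metadata sidecar, CSV,
and a read-only adapter for MATLAB v5 ``.mat`` files as distributed by the
public HD-sEMG benchmarks.  All indices are 0-based; time intervals are
half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ElectrodeGrid",
    "Recording",
    "capgmyo_grid",
    "csl_grid",
    "frame_to_image",
    "image_to_channels",
    "load_recording",
    "save_recording",
]


@dataclass(frozen=True)
class ElectrodeGrid:
    """Grid geometry and the channel -> (row, col) pixel mapping.

    Parameters
    ----------
    rows, cols
        Grid height ``h`` and width ``w``.
    channel_map
        ``(rows * cols, 2)`` integer array; row ``k`` gives the pixel of
        channel ``k``.  Defaults to row-major order (channel 0 at (0, 0),
        channel 1 at (0, 1), ...), which is a convention, not a property of
        the hardware: acquisition systems wire grids differently, so the map
        is user-overridable.
    layout_name
        Free-text identifier for the layout.
    """

    rows: int
    cols: int
    channel_map: np.ndarray = field(default=None)  # type: ignore[assignment]
    layout_name: str = "custom"

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("grid dimensions must be positive")
        cmap = self.channel_map
        if cmap is None:
            rr, cc = np.divmod(np.arange(self.rows * self.cols), self.cols)
            cmap = np.column_stack([rr, cc])
        cmap = np.asarray(cmap, dtype=np.int64)
        if cmap.shape != (self.rows * self.cols, 2):
            raise ValueError(
                f"channel_map shape {cmap.shape} inconsistent with "
                f"{self.rows}x{self.cols} grid"
            )
        pixels = {(int(r), int(c)) for r, c in cmap}
        if len(pixels) != self.rows * self.cols:
            raise ValueError("channel_map is not a bijection onto the grid")
        if cmap[:, 0].min() < 0 or cmap[:, 0].max() >= self.rows:
            raise ValueError("channel_map row index out of range")
        if cmap[:, 1].min() < 0 or cmap[:, 1].max() >= self.cols:
            raise ValueError("channel_map col index out of range")
        object.__setattr__(self, "channel_map", cmap)

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ElectrodeGrid)
            and self.rows == other.rows
            and self.cols == other.cols
            and np.array_equal(self.channel_map, other.channel_map)
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.rows, self.cols, self.channel_map.tobytes()))


def capgmyo_grid() -> ElectrodeGrid:
    """The 8 x 16 monopolar grid layout (128 channels at 1000 Hz)."""
    return ElectrodeGrid(8, 16, layout_name="capgmyo-dba")


def csl_grid() -> ElectrodeGrid:
    """The 7 x 24 usable bipolar-channel layout (168 channels at 2048 Hz).

    Bipolar derivations crossing a column boundary are invalid and already
    absent from this arrangement.
    """
    return ElectrodeGrid(7, 24, layout_name="csl-hdemg")


@dataclass
class Recording:
    """A ``channels x frames`` HD-sEMG signal with grid and metadata."""

    signal: np.ndarray
    fs: float
    grid: ElectrodeGrid
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a 2D channels x frames matrix")
        if self.signal.shape[0] != self.grid.n_channels:
            raise ValueError(
                f"channel/grid mismatch: {self.signal.shape[0]} channels vs "
                f"{self.grid.rows}x{self.grid.cols} grid "
                f"({self.grid.n_channels} expected)"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.signal.shape[1] < 1:
            raise ValueError("recording must contain at least one frame")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_frames(self) -> int:
        return self.signal.shape[1]


def frame_to_image(rec: Recording, frame_index: int) -> np.ndarray:
    """Arrange one time frame into an ``h x w`` instantaneous sEMG image."""
    if not 0 <= frame_index < rec.n_frames:
        raise IndexError(
            f"frame index {frame_index} out of range [0, {rec.n_frames})"
        )
    return frames_to_images(rec, frame_index, frame_index + 1)[0]


def frames_to_images(rec: Recording, start: int, end: int) -> np.ndarray:
    """Vectorized image formation for frames ``[start, end)``.

    Returns an ``(end - start) x h x w`` array where pixel ``(r, c)`` of
    image ``t`` is the sample of the channel mapped to ``(r, c)``.
    """
    if not (0 <= start <= end <= rec.n_frames):
        raise IndexError(f"frame range [{start}, {end}) out of bounds")
    g = rec.grid
    images = np.empty((end - start, g.rows, g.cols), dtype=rec.signal.dtype)
    images[:, g.channel_map[:, 0], g.channel_map[:, 1]] = rec.signal[:, start:end].T
    return images


def image_to_channels(image: np.ndarray, grid: ElectrodeGrid) -> np.ndarray:
    """Invert :func:`frame_to_image`: recover the channel vector of an image."""
    image = np.asarray(image)
    if image.shape != (grid.rows, grid.cols):
        raise ValueError("image shape does not match grid")
    return image[grid.channel_map[:, 0], grid.channel_map[:, 1]]


# ---------------------------------------------------------------------------
# Container I/O
# ---------------------------------------------------------------------------

_FORMATS = ("hdf5", "npy", "csv", "mat")


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    table = {".h5": "hdf5", ".hdf5": "hdf5", ".npy": "npy",
             ".csv": "csv", ".mat": "mat"}
    if suffix not in table:
        raise ValueError(f"cannot infer container format from suffix {suffix!r}")
    return table[suffix]


def save_recording(rec: Recording, path: str | Path, format: str | None = None) -> Path:
    """Write a recording; lossless for HDF5/NPY, decimal-text for CSV."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("signal", data=rec.signal)
            f.attrs["fs"] = float(rec.fs)
            g = f.create_group("grid")
            g.attrs["rows"] = rec.grid.rows
            g.attrs["cols"] = rec.grid.cols
            g.attrs["layout_name"] = rec.grid.layout_name
            g.create_dataset("channel_map", data=rec.grid.channel_map)
            f.attrs["meta"] = json.dumps(rec.meta)
    elif fmt == "npy":
        np.save(path, rec.signal)
        sidecar = path.with_suffix(".json")
        sidecar.write_text(json.dumps({
            "fs": rec.fs,
            "grid": {
                "rows": rec.grid.rows,
                "cols": rec.grid.cols,
                "channel_map": rec.grid.channel_map.tolist(),
                "layout_name": rec.grid.layout_name,
            },
            "meta": rec.meta,
        }))
    elif fmt == "csv":
        header = json.dumps({
            "fs": rec.fs,
            "rows": rec.grid.rows,
            "cols": rec.grid.cols,
            "channel_map": rec.grid.channel_map.tolist(),
            "layout_name": rec.grid.layout_name,
            "meta": rec.meta,
            "orientation": "channels-as-rows",
        })
        np.savetxt(path, rec.signal, delimiter=",", fmt="%.17g",
                   header=header, comments="# ")
    else:
        raise ValueError(
            f"unsupported save format {fmt!r} (supported: hdf5, npy, csv)"
        )
    return path


def load_recording(
    path: str | Path,
    format: str | None = None,
    grid: ElectrodeGrid | None = None,
    frames_as_rows: bool = False,
    mat_key: str = "data",
    fs: float | None = None,
) -> Recording:
    """Read a recording from a supported container.

    Parameters
    ----------
    path, format
        File path; ``format`` in ``{"hdf5", "npy", "csv", "mat"}`` or
        inferred from the suffix.
    grid
        Required for the ``mat`` adapter (the benchmark containers carry no
        geometry); overrides the stored grid otherwise.
    frames_as_rows
        Set if the stored matrix is frames x channels; it is transposed to
        the canonical channels x frames orientation.
    mat_key, fs
        Dataset key and sampling rate for the MATLAB adapter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")

    if fmt == "hdf5":
        import h5py

        with h5py.File(path, "r") as f:
            signal = f["signal"][()]
            fs_read = float(f.attrs["fs"])
            g = f["grid"]
            stored_grid = ElectrodeGrid(
                int(g.attrs["rows"]), int(g.attrs["cols"]),
                channel_map=g["channel_map"][()],
                layout_name=str(g.attrs["layout_name"]),
            )
            meta = json.loads(f.attrs.get("meta", "{}"))
    elif fmt == "npy":
        signal = np.load(path)
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"NPY metadata sidecar missing: {sidecar}")
        info = json.loads(sidecar.read_text())
        fs_read = float(info["fs"])
        gi = info["grid"]
        stored_grid = ElectrodeGrid(
            gi["rows"], gi["cols"],
            channel_map=np.asarray(gi["channel_map"]),
            layout_name=gi.get("layout_name", "custom"),
        )
        meta = info.get("meta", {})
    elif fmt == "csv":
        with open(path) as f:
            first = f.readline()
        info = json.loads(first.lstrip("# ").strip())
        signal = np.loadtxt(path, delimiter=",", ndmin=2)
        fs_read = float(info["fs"])
        stored_grid = ElectrodeGrid(
            info["rows"], info["cols"],
            channel_map=np.asarray(info["channel_map"]),
            layout_name=info.get("layout_name", "custom"),
        )
        meta = info.get("meta", {})
    else:  # mat adapter: read-only, geometry supplied by the caller
        from scipy.io import loadmat

        if grid is None:
            raise ValueError("the MAT adapter requires an explicit grid")
        if fs is None:
            raise ValueError("the MAT adapter requires an explicit fs")
        contents = loadmat(path)
        if mat_key not in contents:
            raise KeyError(
                f"{mat_key!r} not found in {path.name}; available keys: "
                f"{[k for k in contents if not k.startswith('__')]}"
            )
        signal = np.asarray(contents[mat_key], dtype=np.float64)
        # benchmark layout stores frames x channels
        frames_as_rows = True
        fs_read = float(fs)
        stored_grid = grid
        meta = {"source": path.name}

    if frames_as_rows:
        signal = signal.T
    use_grid = grid or stored_grid
    return Recording(signal=signal, fs=fs if fs is not None else fs_read,
                     grid=use_grid, meta=meta)
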