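"""Reading and writing optical-mapping movies, traces, masks and result maps.

Movies are multi-page grayscale TIFF stacks (frames x rows x cols, arbitrary
fluorescence units).  Single traces travel as two-column CSV (time_ms, value).
Result maps are written as delimited text (NaN for masked-out pixels) and,
optionally, single-page float32 TIFF.

Conventions used throughout the package: frame indexing is 0-based and frame
``f`` maps to time ``time_origin + f * 1000 / sampling_rate`` milliseconds;
analysis assumes depolarisation-up signals, so voltage-dye recordings in which
depolarisation darkens the tissue must be read with ``invert=True``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import tifffile


class ValidationError(ValueError):
    """A parameter or input violates a documented precondition."""


class FormatError(ValueError):
    """A file is readable but not in a supported layout."""


@dataclass
class ImageStack:
    """A fluorescence movie with its acquisition geometry.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, n_rows, n_cols)``, arbitrary units.
    sampling_rate
        Frames per second (Hz).
    mask
        Boolean ``(n_rows, n_cols)`` array of analysed pixels.  Defaults to
        all-true.
    pixel_size
        Micrometres per pixel; metadata only.
    time_origin
        Time of frame 0 in milliseconds.
    """

    frames: np.ndarray
    sampling_rate: float
    mask: np.ndarray | None = None
    pixel_size: float | None = None
    time_origin: float = 0.0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValidationError(
                f"frames must be 3-D (frames x rows x cols), got {self.frames.ndim}-D"
            )
        if self.frames.shape[0] < 2:
            raise ValidationError("a movie needs at least 2 frames")
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.mask is None:
            self.mask = np.ones(self.frames.shape[1:], dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.frames.shape[1:]:
                raise ValidationError(
                    f"mask shape {self.mask.shape} != frame shape {self.frames.shape[1:]}"
                )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def frame_interval_ms(self) -> float:
        """Time between consecutive frames in milliseconds."""
        return 1000.0 / self.sampling_rate

    def times_ms(self) -> np.ndarray:
        """Time of every frame in milliseconds (exact linear mapping)."""
        return self.time_origin + np.arange(self.n_frames) * (1000.0 / self.sampling_rate)

    def frame_time(self, f: int) -> float:
        return self.time_origin + f * (1000.0 / self.sampling_rate)

    def with_frames(self, frames: np.ndarray) -> "ImageStack":
        """Copy of this stack with replaced frame data (same geometry)."""
        return ImageStack(
            frames=frames,
            sampling_rate=self.sampling_rate,
            mask=self.mask.copy(),
            pixel_size=self.pixel_size,
            time_origin=self.time_origin,
        )


@dataclass
class Trace:
    """A single 1-D fluorescence or voltage signal."""

    values: np.ndarray
    sampling_rate: float
    label: str = ""
    time_origin: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64).ravel()
        if self.values.size < 2:
            raise ValidationError("a trace needs at least 2 samples")
        if not self.sampling_rate > 0:
            raise ValidationError(f"sampling_rate must be > 0, got {self.sampling_rate}")

    def times_ms(self) -> np.ndarray:
        return self.time_origin + np.arange(self.values.size) * (1000.0 / self.sampling_rate)

    def as_stack(self) -> ImageStack:
        """View this trace as a 1x1-pixel movie."""
        return ImageStack(
            frames=self.values[:, None, None],
            sampling_rate=self.sampling_rate,
            time_origin=self.time_origin,
        )


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def _invert_frames(frames: np.ndarray) -> np.ndarray:
    # negate, then shift so the global minimum is exactly 0
    out = -frames
    return out - out.min()


def read_stack(path: str | Path, sampling_rate: float, invert: bool = False) -> ImageStack:
    """Read a movie from a multi-page grayscale TIFF or a 2-column trace CSV.

    A delimited-text file (time_ms, value) yields a 1x1-pixel stack so that
    single traces flow through the same pipeline as movies.

    ``invert`` negates the data and shifts it so its minimum is 0, for dyes
    that report depolarisation as a fluorescence decrease.
    """
    path = Path(path)
    if not sampling_rate > 0:
        raise ValidationError(f"sampling_rate must be > 0, got {sampling_rate}")
    if not path.exists():
        raise IOError(f"cannot read optical-mapping file: {path}")

    if path.suffix.lower() in (".tif", ".tiff"):
        try:
            frames = tifffile.imread(str(path))
        except Exception as exc:  # pragma: no cover - tifffile error text varies
            raise IOError(f"cannot read TIFF stack {path}: {exc}") from exc
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None]
        if frames.ndim != 3:
            raise FormatError(
                f"{path}: expected grayscale pages (frames x rows x cols), got shape {frames.shape}"
            )
        frames = frames.astype(np.float64)
    else:
        trace = read_trace(path, sampling_rate=sampling_rate)
        frames = trace.values[:, None, None]

    if invert:
        frames = _invert_frames(frames)
    return ImageStack(frames=frames, sampling_rate=sampling_rate)


def read_trace(path: str | Path, sampling_rate: float | None = None) -> Trace:
    """Read a 2-column (time_ms, value) delimited-text trace.

    The sampling rate is inferred from the time column unless given; a
    supplied rate that disagrees with the time column by >1% raises.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"cannot read trace file: {path}")
    try:
        data = np.loadtxt(str(path), delimiter=",", comments="#", skiprows=0)
    except ValueError:
        # tolerate a single header line
        data = np.loadtxt(str(path), delimiter=",", comments="#", skiprows=1)
    data = np.atleast_2d(data)
    if data.shape[1] != 2:
        raise FormatError(
            f"{path}: trace files must have exactly 2 columns (time_ms,value), got {data.shape[1]}"
        )
    t, v = data[:, 0], data[:, 1]
    if t.size < 2:
        raise FormatError(f"{path}: trace needs at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise FormatError(f"{path}: time column must be strictly increasing")
    rate_from_file = 1000.0 / float(np.mean(dt))
    if sampling_rate is None:
        sampling_rate = rate_from_file
    elif abs(sampling_rate - rate_from_file) > 0.01 * rate_from_file:
        raise ValidationError(
            f"supplied sampling_rate {sampling_rate} Hz disagrees with time column "
            f"({rate_from_file:.3f} Hz) in {path}"
        )
    return Trace(values=v, sampling_rate=sampling_rate, label=path.stem, time_origin=float(t[0]))


def write_trace(trace: Trace, path: str | Path) -> None:
    """Write a trace as 2-column CSV (time_ms,value)."""
    path = Path(path)
    data = np.column_stack([trace.times_ms(), trace.values])
    np.savetxt(str(path), data, delimiter=",", header="time_ms,value", comments="")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a movie as a multi-page float32 TIFF."""
    tifffile.imwrite(str(Path(path)), stack.frames.astype(np.float32),
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# result maps
# ---------------------------------------------------------------------------

def write_map(
    map_values: np.ndarray,
    mask: np.ndarray | None,
    path: str | Path,
    also_tiff: bool = False,
) -> None:
    """Write a per-pixel result map as delimited text.

    Masked-out pixels are written as the literal token ``NaN``.  When
    ``also_tiff`` is set, a single-page float32 TIFF is written alongside
    (same stem, ``.tif`` suffix).
    """
    path = Path(path)
    map_values = np.asarray(map_values, dtype=np.float64)
    if map_values.ndim != 2:
        raise ValidationError("map must be 2-D")
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != map_values.shape:
            raise ValidationError(
                f"mask shape {mask.shape} != map shape {map_values.shape}"
            )
        map_values = np.where(mask, map_values, np.nan)
    np.savetxt(str(path), map_values.astype(np.float32), delimiter=",", fmt="%.9g")
    if also_tiff:
        tifffile.imwrite(str(path.with_suffix(".tif")), map_values.astype(np.float32),
                         photometric="minisblack")


def read_map(path: str | Path) -> np.ndarray:
    """Read a delimited-text map written by :func:`write_map` (NaNs preserved)."""
    arr = np.genfromtxt(str(Path(path)), delimiter=",", dtype=np.float32)
    return np.atleast_2d(np.asarray(arr, dtype=np.float64))


def read_mask(path: str | Path) -> np.ndarray:
    """Read a pixel mask from single-page TIFF (0/255) or CSV of 0/1."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = np.asarray(tifffile.imread(str(path)))
    else:
        arr = np.atleast_2d(np.loadtxt(str(path), delimiter=","))
    if arr.ndim != 2:
        raise FormatError(f"{path}: mask must be a single 2-D page")
    return arr > 0


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    path = Path(path)
    mask = np.asarray(mask, dtype=bool)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), (mask * np.uint8(255)), photometric="minisblack")
    else:
        np.savetxt(str(path), mask.astype(np.uint8), delimiter=",", fmt="%d")
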