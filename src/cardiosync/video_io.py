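"""Image-stack I/O, ΔF/F0 normalization and spatial binning.

The raw input of the pipeline is a time-lapse fluorescence recording of a
calcium-indicator-loaded culture (e.g. Fluo-4), stored as a multi-page
grayscale TIFF (primary) or any container imageio can decode. Intensities
are converted to floating point on load; the source dtype is recorded.

ΔF/F0 uses a per-pixel temporal-quantile baseline, the standard
normalization for single-wavelength calcium dyes: transients occupy a
minority of frames, so a low quantile of each pixel's time series is a
robust estimate of the resting fluorescence F0.

"Local" analysis is realized by partitioning the field of view into a
rectangular grid of bins (default 16×16 px, roughly one cell at 10×
magnification) and averaging ΔF/F0 within each bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import DegenerateInputError, InputFormatError, ParameterError

__all__ = [
    "VideoStack",
    "RegionGrid",
    "Trace",
    "load_stack",
    "save_stack",
    "delta_f_over_f0",
    "bin_regions",
    "traces_to_dataframe",
    "write_traces_csv",
    "read_traces_csv",
]

#: Relative floor applied to per-pixel baselines, as a fraction of the
#: global intensity maximum, to avoid division blow-up on dim pixels.
BASELINE_EPS_FRACTION = 1e-6

_TIFF_SUFFIXES = {".tif", ".tiff"}


@dataclass
class VideoStack:
    """A (T, H, W) intensity stack with a fixed frame interval.

    Parameters
    ----------
    frames
        3-D float array indexed (t, row, col); row 0 / col 0 is the
        top-left corner, all indices 0-based.
    frame_interval
        Seconds per frame (> 0).
    pixel_size
        µm per pixel, or ``None`` when unknown.
    source_dtype
        dtype of the file the stack was loaded from, if any.
    """

    frames: np.ndarray
    frame_interval: float
    pixel_size: float | None = None
    source_dtype: np.dtype | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ParameterError(
                f"frames must be 3-D (t, row, col), got ndim={self.frames.ndim}"
            )
        t, h, w = self.frames.shape
        if t < 2:
            raise DegenerateInputError(f"need at least 2 frames, got {t}")
        if h < 1 or w < 1:
            raise DegenerateInputError(f"empty frame shape {h}x{w}")
        if not (self.frame_interval > 0):
            raise ParameterError(f"frame_interval must be > 0, got {self.frame_interval}")
        if not np.all(np.isfinite(self.frames)):
            raise ParameterError("frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    @property
    def duration(self) -> float:
        """Total recording span in seconds (T × frame interval)."""
        return self.n_frames * self.frame_interval

    @property
    def times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds, starting at 0."""
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class RegionGrid:
    """Partition of the field of view into rectangular analysis bins.

    Bins tile the frame in row-major order; edge bins may be smaller than
    ``bin_rows`` × ``bin_cols``. Every pixel belongs to exactly one region.
    """

    bin_rows: int
    bin_cols: int
    region_index: np.ndarray  # (H, W) int array, pixel -> region id
    grid_shape: tuple[int, int]  # (n_bin_rows, n_bin_cols)

    @property
    def n_regions(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    @property
    def region_sizes(self) -> np.ndarray:
        """Pixel count per region id."""
        return np.bincount(self.region_index.ravel(), minlength=self.n_regions)


@dataclass
class Trace:
    """A per-region ΔF/F0 (or motion-energy) time series."""

    values: np.ndarray
    frame_interval: float
    region_id: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1:
            raise ParameterError("trace values must be 1-D")
        if not (self.frame_interval > 0):
            raise ParameterError("frame_interval must be > 0")
        if not np.all(np.isfinite(self.values)):
            raise ParameterError("trace contains non-finite values")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self)) * self.frame_interval

    @property
    def duration(self) -> float:
        return len(self) * self.frame_interval


def _reduce_channels(arr: np.ndarray) -> np.ndarray:
    """Collapse a trailing channel axis by averaging.

    Calcium recordings are single-dye, so RGB(A) containers carry redundant
    channels; an alpha channel (4th) is excluded from the mean.
    """
    if arr.ndim == 4:
        n_ch = arr.shape[-1]
        if n_ch == 4:
            arr = arr[..., :3]
        return arr.mean(axis=-1)
    return arr


def load_stack(path: str | Path, frame_interval: float) -> VideoStack:
    """Read a multi-page TIFF (or imageio-readable video) as a VideoStack.

    Multi-channel inputs are reduced to one channel by averaging (alpha
    excluded). Intensities must be nonnegative.

    Raises
    ------
    InputFormatError
        If the file cannot be decoded.
    DegenerateInputError
        If the file holds fewer than 2 frames.
    """
    path = Path(path)
    if not (frame_interval > 0):
        raise ParameterError(f"frame_interval must be > 0, got {frame_interval}")
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        else:
            import imageio.v3 as iio

            arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # decoder-specific failure classes vary
        raise InputFormatError(f"could not read image stack {path}: {exc}") from exc

    arr = np.asarray(arr)
    source_dtype = arr.dtype
    if arr.ndim == 2:
        raise DegenerateInputError(
            f"{path} holds a single frame; a time series needs at least 2"
        )
    if arr.ndim == 3 and arr.shape[-1] in (3, 4) and arr.shape[0] not in (3, 4):
        # single RGB frame disguised as (H, W, C)
        raise DegenerateInputError(
            f"{path} holds a single multi-channel frame; need a time series"
        )
    arr = _reduce_channels(arr)
    if arr.ndim != 3:
        raise InputFormatError(
            f"{path}: expected a (t, row, col) stack, got shape {arr.shape}"
        )
    arr = arr.astype(np.float64)
    if arr.min() < 0:
        raise InputFormatError(f"{path}: negative intensities in raw stack")
    return VideoStack(arr, frame_interval=frame_interval, source_dtype=source_dtype)


def save_stack(video: VideoStack, path: str | Path, dtype=np.float32) -> None:
    """Write a VideoStack as a multi-page TIFF.

    Integer ``dtype`` preserves integer-valued stacks bit-exactly on
    reload; the default float32 is used for derived (ΔF/F0) stacks.
    """
    # explicit photometric: a (3, H, W) stack must not be guessed as RGB
    tifffile.imwrite(Path(path), video.frames.astype(dtype), photometric="minisblack")


def delta_f_over_f0(video: VideoStack, baseline_quantile: float = 0.10) -> VideoStack:
    """Normalize a raw stack to ΔF/F0 with a per-pixel quantile baseline.

    F0 is the ``baseline_quantile`` quantile of each pixel's time series,
    floored at a small positive epsilon (1e-6 of the global maximum);
    the output is (F − F0)/F0. Pixels that are zero at every frame yield 0
    rather than a division artifact. Output values can be negative
    (below-baseline excursions).
    """
    if not (0 < baseline_quantile < 0.5):
        raise ParameterError(
            f"baseline_quantile must be in (0, 0.5), got {baseline_quantile}"
        )
    frames = video.frames
    f0 = np.quantile(frames, baseline_quantile, axis=0)
    global_max = frames.max()
    if global_max <= 0:
        dff = np.zeros_like(frames)
    else:
        eps = BASELINE_EPS_FRACTION * global_max
        f0 = np.maximum(f0, eps)
        dff = (frames - f0) / f0
        dead = frames.max(axis=0) <= 0  # all-zero pixels stay at 0
        if dead.any():
            dff[:, dead] = 0.0
    return VideoStack(
        dff,
        frame_interval=video.frame_interval,
        pixel_size=video.pixel_size,
        source_dtype=video.source_dtype,
    )


def bin_regions(
    video: VideoStack, bin_rows: int = 16, bin_cols: int = 16
) -> tuple[RegionGrid, list[Trace]]:
    """Partition the frame into bins and average each bin's pixels per frame.

    Regions tile the frame as ``ceil(H/bin_rows) × ceil(W/bin_cols)``
    rectangles in row-major order; edge regions may be smaller. Each
    region's trace is the arithmetic mean of its pixels at every frame.
    """
    t, h, w = video.shape
    if not (1 <= bin_rows <= h) or not (1 <= bin_cols <= w):
        raise ParameterError(
            f"bin {bin_rows}x{bin_cols} out of range for frame {h}x{w}"
        )
    n_br = -(-h // bin_rows)
    n_bc = -(-w // bin_cols)
    row_bin = np.arange(h) // bin_rows
    col_bin = np.arange(w) // bin_cols
    region_index = (row_bin[:, None] * n_bc + col_bin[None, :]).astype(np.int64)
    grid = RegionGrid(bin_rows, bin_cols, region_index, (n_br, n_bc))

    row_edges = np.arange(0, h, bin_rows)
    col_edges = np.arange(0, w, bin_cols)
    sums = np.add.reduceat(video.frames, row_edges, axis=1)
    sums = np.add.reduceat(sums, col_edges, axis=2)  # (T, n_br, n_bc)
    counts = grid.region_sizes.reshape(n_br, n_bc)
    means = sums / counts[None, :, :]
    traces = [
        Trace(means[:, r, c], video.frame_interval, region_id=r * n_bc + c)
        for r in range(n_br)
        for c in range(n_bc)
    ]
    return grid, traces


def traces_to_dataframe(traces: list[Trace]) -> pd.DataFrame:
    """Long-format table with columns (region_id, frame, time_s, dff)."""
    parts = []
    for tr in traces:
        parts.append(
            pd.DataFrame(
                {
                    "region_id": tr.region_id,
                    "frame": np.arange(len(tr)),
                    "time_s": tr.times,
                    "dff": tr.values,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)


def write_traces_csv(traces: list[Trace], path: str | Path) -> None:
    traces_to_dataframe(traces).to_csv(path, index=False)


def read_traces_csv(path: str | Path) -> list[Trace]:
    """Inverse of :func:`write_traces_csv` (frame interval inferred per region)."""
    df = pd.read_csv(path)
    traces = []
    for rid, grp in df.groupby("region_id", sort=True):
        grp = grp.sort_values("frame")
        times = grp["time_s"].to_numpy()
        if len(times) < 2:
            raise DegenerateInputError(f"region {rid}: fewer than 2 samples")
        dt = float(np.median(np.diff(times)))
        traces.append(Trace(grp["dff"].to_numpy(), dt, region_id=int(rid)))
    return traces
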