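"""Local beating-frequency and signed phase-lag maps.

Each analysis region's peak train is summarized into (a) a beating
frequency, estimated as (n − 1)/(t_last − t_first) — unbiased for partial
recording windows and insensitive to silent lead-in frames — and (b) a
signed phase lag against a population reference, defined as the peaks of
the whole-field mean trace. The sign convention is physiological:
**positive phase = the region beats earlier than the population**,
negative = retarded.

Regions with fewer than 2 peaks are inactive and carry NaN, never 0 (a
silent region is not a 0 Hz oscillator).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisUnavailableError, ParameterError
from .peakfind import PeakList, PeakParams, find_peaks
from .video_io import RegionGrid, Trace

__all__ = [
    "FrequencyMap",
    "PhaseMap",
    "frequency_map",
    "reference_beats",
    "phase_map",
    "maps_to_dataframe",
    "map_to_image",
    "save_map_tiff",
    "save_map_png",
]


@dataclass
class FrequencyMap:
    """Per-region beating frequency (Hz) with an activity mask.

    ``values_hz[i]`` is NaN where ``active[i]`` is False (fewer than 2
    detected transients).
    """

    values_hz: np.ndarray
    active: np.ndarray  # bool
    n_peaks: np.ndarray  # int, per region
    grid_shape: tuple[int, int] | None = None

    @property
    def values_bpm(self) -> np.ndarray:
        """Beats-per-minute view (60 × Hz)."""
        return self.values_hz * 60.0

    @property
    def n_regions(self) -> int:
        return int(self.values_hz.shape[0])


@dataclass
class PhaseMap:
    """Per-region mean signed lag (seconds) against a beat reference.

    Positive = the region's matched peaks precede the reference on
    average (earlier beating); NaN where no regional peak matched.
    """

    values_s: np.ndarray
    reference_beats: np.ndarray  # seconds
    n_matched: np.ndarray  # matched peak pairs per region
    grid_shape: tuple[int, int] | None = None

    @property
    def n_regions(self) -> int:
        return int(self.values_s.shape[0])


def frequency_map(
    peaklists: list[PeakList],
    duration: float,
    grid_shape: tuple[int, int] | None = None,
) -> FrequencyMap:
    """Estimate each region's beating frequency from its peak train.

    For a region with n ≥ 2 peaks the frequency is (n − 1) divided by the
    span between its first and last peak; regions with fewer peaks are
    inactive (NaN).
    """
    if not (duration > 0):
        raise ParameterError("duration must be > 0")
    n = len(peaklists)
    values = np.full(n, np.nan)
    active = np.zeros(n, dtype=bool)
    n_peaks = np.zeros(n, dtype=np.int64)
    for i, pl in enumerate(peaklists):
        n_peaks[i] = pl.count
        if pl.count >= 2:
            span = pl.times[-1] - pl.times[0]
            if span > 0:
                values[i] = (pl.count - 1) / span
                active[i] = True
    return FrequencyMap(values, active, n_peaks, grid_shape)


def reference_beats(global_trace: Trace, params: PeakParams | None = None) -> np.ndarray:
    """Population beat times: peaks of the whole-field mean ΔF/F0 trace.

    Raises
    ------
    AnalysisUnavailableError
        If fewer than 2 reference beats are found (phase and synchrony
        analysis need a beat interval).
    """
    peaks = find_peaks(global_trace, params)
    if peaks.count < 2:
        raise AnalysisUnavailableError(
            f"only {peaks.count} reference beat(s) detected; "
            "phase analysis needs at least 2"
        )
    return peaks.times


def phase_map(
    peaklists: list[PeakList],
    reference: np.ndarray,
    grid_shape: tuple[int, int] | None = None,
) -> PhaseMap:
    """Mean signed lag of each region's peaks against reference beats.

    Every regional peak is matched to the nearest reference beat when the
    two are within ± half the reference mean inter-beat interval (which
    makes the nearest match unique); unmatched peaks are ignored. The
    region's value is the mean of (t_reference − t_region) over matched
    pairs, so a region that fires *before* the reference gets a positive
    phase.
    """
    reference = np.asarray(reference, dtype=np.float64)
    if reference.shape[0] < 2:
        raise ParameterError("reference must contain at least 2 beats")
    if np.any(np.diff(reference) <= 0):
        raise ParameterError("reference beats must be strictly increasing")
    half_window = float(np.mean(np.diff(reference))) / 2.0

    n = len(peaklists)
    values = np.full(n, np.nan)
    n_matched = np.zeros(n, dtype=np.int64)
    for i, pl in enumerate(peaklists):
        if pl.count == 0:
            continue
        t = pl.times
        pos = np.searchsorted(reference, t)
        pos_lo = np.clip(pos - 1, 0, reference.shape[0] - 1)
        pos_hi = np.clip(pos, 0, reference.shape[0] - 1)
        d_lo = np.abs(t - reference[pos_lo])
        d_hi = np.abs(t - reference[pos_hi])
        nearest = np.where(d_lo <= d_hi, pos_lo, pos_hi)
        dist = np.minimum(d_lo, d_hi)
        matched = dist <= half_window
        if matched.any():
            lags = reference[nearest[matched]] - t[matched]
            values[i] = float(lags.mean())
            n_matched[i] = int(matched.sum())
    return PhaseMap(values, reference, n_matched, grid_shape)


def maps_to_dataframe(freq: FrequencyMap, phase: PhaseMap | None = None) -> pd.DataFrame:
    """Tabular view: (region_id, freq_hz, freq_bpm, phase_s, n_peaks)."""
    df = pd.DataFrame(
        {
            "region_id": np.arange(freq.n_regions),
            "freq_hz": freq.values_hz,
            "freq_bpm": freq.values_bpm,
            "n_peaks": freq.n_peaks,
        }
    )
    df["phase_s"] = phase.values_s if phase is not None else np.nan
    return df[["region_id", "freq_hz", "freq_bpm", "phase_s", "n_peaks"]]


def map_to_image(values: np.ndarray, grid_shape: tuple[int, int]) -> np.ndarray:
    """Reshape flat per-region values to the (bin_rows, bin_cols) grid."""
    return np.asarray(values, dtype=np.float32).reshape(grid_shape)


def _upsample(img: np.ndarray, grid: RegionGrid) -> np.ndarray:
    out = np.repeat(img, grid.bin_rows, axis=0)
    out = np.repeat(out, grid.bin_cols, axis=1)
    return out[: grid.region_index.shape[0], : grid.region_index.shape[1]]


def save_map_tiff(
    values: np.ndarray,
    grid: RegionGrid,
    path: str | Path,
    full_resolution: bool = True,
) -> None:
    """Write a per-region map as a 32-bit float TIFF (undefined = NaN)."""
    import tifffile

    img = map_to_image(values, grid.grid_shape)
    if full_resolution:
        img = _upsample(img, grid)
    tifffile.imwrite(Path(path), img.astype(np.float32))


def save_map_png(
    values: np.ndarray,
    grid_shape: tuple[int, int],
    path: str | Path,
    kind: str = "frequency",
    title: str | None = None,
) -> None:
    """Render a map as a PNG: sequential colormap for frequency, diverging
    (centered at 0) for phase."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    img = map_to_image(values, grid_shape)
    fig, ax = plt.subplots(figsize=(5, 4))
    if kind == "phase":
        lim = np.nanmax(np.abs(img)) if np.isfinite(img).any() else 1.0
        lim = lim if lim > 0 else 1.0
        im = ax.imshow(img, cmap="RdBu_r", vmin=-lim, vmax=lim)
        label = "phase lag (s), + = earlier"
    else:
        im = ax.imshow(img, cmap="viridis")
        label = "frequency (Hz)"
    fig.colorbar(im, ax=ax, label=label)
    ax.set_title(title or kind)
    ax.set_xticks([])
    ax.set_yticks([])
    fig.savefig(Path(path), dpi=120, bbox_inches="tight")
    plt.close(fig)
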