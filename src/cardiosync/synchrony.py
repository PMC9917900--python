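"""Per-well synchrony classification and beating-rate quantification.

A well is called synchronously beating when most of its active regions
agree with the well's modal frequency and show small phase lag against
the population reference. The thresholds are explicit and configurable
(the underlying experimental call is usually made by eye); defaults are
conservative: ≥ 80% of active regions within 10% of the modal frequency
and within 10% of the modal period in phase, with at least 25% of regions
active at all.

Mechanical beating rate is computed from brightfield/motion videos via a
frame-differencing energy signal. Because frame-difference energy peaks
on both the contraction and the relaxation stroke, rate extraction from
motion defaults to two-peaks-per-cycle; calcium traces peak once per beat.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .activity_maps import FrequencyMap, PhaseMap
from .errors import DegenerateInputError, ParameterError
from .peakfind import PeakParams, find_peaks
from .video_io import Trace, VideoStack

__all__ = [
    "SynchronyParams",
    "SynchronyReport",
    "modal_frequency",
    "classify_well",
    "percent_synchronous_wells",
    "motion_signal",
    "beating_rate_bpm",
]

#: Width of the histogram bins used to find the modal frequency, Hz.
MODAL_FREQ_BIN_HZ = 0.1

#: Default peak filters for motion-energy signals. The frame-difference
#: signal rides on a noise pedestal (mean |ΔI| of sensor noise), so a
#: prominence criterion — height above the surrounding pedestal — is the
#: robust discriminator, not an absolute height floor.
MOTION_PEAK_PARAMS = PeakParams(min_height=0.0, min_distance=0.1, min_prominence=0.25)


@dataclass(frozen=True)
class SynchronyParams:
    """Thresholds for the per-well synchrony decision (all in (0, 1]).

    freq_tolerance : allowed relative deviation from the modal frequency.
    phase_tolerance : allowed |phase| as a fraction of the modal period.
    min_active_fraction : minimum fraction of regions that must be active.
    min_sync_fraction : minimum fraction of active regions in sync.
    """

    freq_tolerance: float = 0.10
    phase_tolerance: float = 0.10
    min_active_fraction: float = 0.25
    min_sync_fraction: float = 0.80

    def __post_init__(self) -> None:
        for name in (
            "freq_tolerance",
            "phase_tolerance",
            "min_active_fraction",
            "min_sync_fraction",
        ):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ParameterError(f"{name} must be in (0, 1], got {v}")


@dataclass
class SynchronyReport:
    """Outcome of :func:`classify_well` for one well."""

    per_region_sync: np.ndarray  # bool over regions (False where inactive)
    well_synchronous: bool
    sync_fraction: float  # fraction of *active* regions in sync (NaN if none)
    active_fraction: float
    modal_frequency_hz: float  # NaN if no active region


def modal_frequency(freqs_hz: np.ndarray, bin_hz: float = MODAL_FREQ_BIN_HZ) -> float:
    """Mode of a set of frequencies, histogram-binned at ``bin_hz``.

    Ties between equally populated bins resolve to the lower frequency;
    the returned value is the mean of the frequencies in the modal bin.
    NaN entries are ignored; all-NaN input yields NaN.
    """
    freqs_hz = np.asarray(freqs_hz, dtype=np.float64)
    freqs_hz = freqs_hz[np.isfinite(freqs_hz)]
    if freqs_hz.size == 0:
        return float("nan")
    bins = np.floor(freqs_hz / bin_hz + 1e-9).astype(np.int64)
    ids, counts = np.unique(bins, return_counts=True)  # ids ascending
    modal_bin = ids[np.argmax(counts)]  # argmax -> first max -> lowest bin
    return float(freqs_hz[bins == modal_bin].mean())


def classify_well(
    freq: FrequencyMap,
    phase: PhaseMap,
    params: SynchronyParams | None = None,
) -> SynchronyReport:
    """Decide whether a well beats synchronously.

    A region counts as synchronous when it is active, its frequency lies
    within ``freq_tolerance`` (relative) of the well's modal frequency,
    and its |phase| is at most ``phase_tolerance`` modal periods. The well
    is synchronous when the active fraction and the in-sync fraction of
    active regions both clear their thresholds. A well with no active
    regions is not synchronous and has undefined sync_fraction.
    """
    if params is None:
        params = SynchronyParams()
    if freq.n_regions != phase.n_regions:
        raise ParameterError("frequency and phase maps cover different regions")
    n = freq.n_regions
    active = freq.active
    n_active = int(active.sum())
    active_fraction = n_active / n if n else 0.0
    f_modal = modal_frequency(freq.values_hz[active]) if n_active else float("nan")

    sync = np.zeros(n, dtype=bool)
    if n_active and np.isfinite(f_modal) and f_modal > 0:
        freq_ok = np.abs(freq.values_hz - f_modal) <= params.freq_tolerance * f_modal
        phase_ok = np.abs(phase.values_s) <= params.phase_tolerance / f_modal
        sync = active & np.nan_to_num(freq_ok, nan=False) & np.nan_to_num(phase_ok, nan=False)

    sync_fraction = float(sync.sum() / n_active) if n_active else float("nan")
    well_synchronous = bool(
        n_active
        and active_fraction >= params.min_active_fraction
        and sync_fraction >= params.min_sync_fraction
    )
    return SynchronyReport(sync, well_synchronous, sync_fraction, active_fraction, f_modal)


def percent_synchronous_wells(decisions: pd.DataFrame) -> pd.DataFrame:
    """Percentage of synchronous wells per condition and day.

    ``decisions`` needs columns (condition, day, synchronous); each row is
    one well. Returns (condition, day, n_wells, percent_synchronous) with
    percent = 100 × synchronous / total, exact for integer counts.
    """
    required = {"condition", "day", "synchronous"}
    missing = required - set(decisions.columns)
    if missing:
        raise ParameterError(f"decisions table missing columns: {sorted(missing)}")
    if decisions.empty:
        raise ParameterError("decisions table is empty")
    grouped = decisions.groupby(["condition", "day"], sort=True)["synchronous"]
    out = grouped.agg(n_wells="size", n_sync="sum").reset_index()
    out["percent_synchronous"] = 100.0 * out["n_sync"] / out["n_wells"]
    return out[["condition", "day", "n_wells", "percent_synchronous"]]


def motion_signal(video: VideoStack) -> Trace:
    """Frame-differencing motion-energy signal of a video.

    Value at frame t ≥ 1 is the mean absolute intensity change from the
    previous frame, normalized to the signal's own 95th percentile; frame
    0 is 0 by convention. A static video yields an all-zero signal.
    """
    if video.n_frames < 3:
        raise DegenerateInputError("motion analysis needs at least 3 frames")
    diffs = np.abs(np.diff(video.frames, axis=0)).mean(axis=(1, 2))
    signal = np.concatenate([[0.0], diffs])
    scale = np.percentile(signal[1:], 95)
    if scale > 0:
        signal = signal / scale
    return Trace(signal, video.frame_interval, region_id=0)


def beating_rate_bpm(
    motion: Trace,
    params: PeakParams | None = None,
    mode: str = "two-peaks-per-cycle",
) -> float:
    """Beating rate in bpm from a motion-energy (or calcium) trace.

    Peaks of the trace are detected and converted to a frequency via
    (n − 1)/span; in ``two-peaks-per-cycle`` mode (frame-difference
    signals, which fire on contraction *and* relaxation) the result is
    halved. When ``params`` is None the pedestal-robust
    :data:`MOTION_PEAK_PARAMS` defaults are used. Returns NaN when fewer
    than 2 peaks are found.
    """
    if mode not in ("one-peak-per-cycle", "two-peaks-per-cycle"):
        raise ParameterError(f"unknown mode {mode!r}")
    if params is None:
        params = MOTION_PEAK_PARAMS
    peaks = find_peaks(motion, params)
    if peaks.count < 2:
        return float("nan")
    span = peaks.times[-1] - peaks.times[0]
    if span <= 0:
        return float("nan")
    rate = 60.0 * (peaks.count - 1) / span
    if mode == "two-peaks-per-cycle":
        rate /= 2.0
    return rate
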