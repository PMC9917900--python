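"""Scalar quantifications outside the video pipeline.

Two measurements are implemented here:

* **Troponin-T area fraction** — the differentiation score of an
  immunofluorescence image: the percentage of the field covered by
  marker-positive pixels, normalized by the fraction of potentially
  differentiating cells seeded (default 0.30, i.e. a 30%:70%
  myoblast:fibroblast co-culture). Positivity defaults to an Otsu
  threshold on the marker channel; an explicit threshold can be given.
  Normalized scores above 100% (possible when the seeded population
  outgrows its seeding fraction) are reported as computed and flagged,
  never clipped.

* **Dynamic-mechanical-analysis moduli** — for an oscillatory
  compression test with stress amplitude σ0, strain amplitude ε0 and
  stress–strain phase angle δ:

      E′ = (σ0/ε0)·cos δ      (storage modulus)
      E″ = (σ0/ε0)·sin δ      (loss modulus)
      E  = √(E′² + E″²) = σ0/ε0   (Young's modulus)

  The quotient σ0/ε0 is the only reading that carries modulus units and
  makes the Young's-modulus identity exact.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import cos, hypot, pi, sin

import numpy as np
import pandas as pd

from .errors import AnalysisUnavailableError, ParameterError

__all__ = [
    "FluorescenceImage",
    "MechanicalSample",
    "TroponinScore",
    "troponin_area_fraction",
    "storage_modulus",
    "loss_modulus",
    "young_modulus",
    "dma_table",
]

#: Seeding fraction of differentiation-competent cells in the standard
#: 30%:70% co-culture.
DEFAULT_SEEDED_FRACTION = 0.30


@dataclass
class FluorescenceImage:
    """A marker channel with an optional counterstain channel."""

    marker: np.ndarray
    counterstain: np.ndarray | None = None
    pixel_size: float | None = None

    def __post_init__(self) -> None:
        self.marker = np.asarray(self.marker, dtype=np.float64)
        if self.marker.ndim != 2:
            raise ParameterError("marker channel must be 2-D")
        if not np.all(np.isfinite(self.marker)) or self.marker.min() < 0:
            raise ParameterError("marker intensities must be finite and >= 0")
        if self.counterstain is not None:
            self.counterstain = np.asarray(self.counterstain, dtype=np.float64)
            if self.counterstain.shape != self.marker.shape:
                raise ParameterError("channel shapes differ")


@dataclass(frozen=True)
class MechanicalSample:
    """One oscillatory-test measurement: σ0 (kPa), ε0 (–), δ (rad)."""

    sigma0: float
    epsilon0: float
    delta: float

    def __post_init__(self) -> None:
        if self.sigma0 < 0:
            raise ParameterError("stress amplitude sigma0 must be >= 0")
        if not (self.epsilon0 > 0):
            raise ParameterError("strain amplitude epsilon0 must be > 0")
        if not (0 <= self.delta <= pi / 2):
            raise ParameterError("phase angle delta must lie in [0, pi/2]")


@dataclass
class TroponinScore:
    """Raw and seeding-normalized marker area percentages."""

    raw_percent: float
    normalized_percent: float
    threshold: float
    exceeds_100: bool  # normalized score above 100% (flagged, not clipped)


def troponin_area_fraction(
    image: FluorescenceImage,
    seeded_fraction: float = DEFAULT_SEEDED_FRACTION,
    threshold: float | None = None,
) -> TroponinScore:
    """Marker-positive area percentage, normalized by seeding fraction.

    raw % = 100 × (pixels strictly above threshold) / total pixels;
    normalized % = raw % / seeded_fraction. The threshold defaults to
    Otsu's criterion on the marker channel.

    Raises
    ------
    AnalysisUnavailableError
        If the marker channel is uniform and no explicit threshold is
        given (Otsu is undefined on a single-level histogram).
    """
    if not (0 < seeded_fraction <= 1):
        raise ParameterError(f"seeded_fraction must be in (0, 1], got {seeded_fraction}")
    marker = image.marker
    if threshold is None:
        if marker.max() == marker.min():
            raise AnalysisUnavailableError(
                "uniform marker channel: automatic (Otsu) threshold undefined; "
                "pass an explicit threshold"
            )
        from skimage.filters import threshold_otsu

        threshold = float(threshold_otsu(marker))
    raw = 100.0 * float(np.count_nonzero(marker > threshold)) / marker.size
    normalized = raw / seeded_fraction
    return TroponinScore(raw, normalized, float(threshold), normalized > 100.0)


def storage_modulus(s: MechanicalSample) -> float:
    """Elastic (in-phase) stiffness component E′ = (σ0/ε0)·cos δ, kPa."""
    return s.sigma0 / s.epsilon0 * cos(s.delta)


def loss_modulus(s: MechanicalSample) -> float:
    """Viscous (out-of-phase) component E″ = (σ0/ε0)·sin δ, kPa."""
    return s.sigma0 / s.epsilon0 * sin(s.delta)


def young_modulus(s: MechanicalSample) -> float:
    """Young's modulus E = √(E′² + E″²), identically σ0/ε0, kPa."""
    return hypot(storage_modulus(s), loss_modulus(s))


def dma_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Vectorized moduli over a table with columns
    (sigma0_kpa, epsilon0, delta_rad); adds E_storage, E_loss, E_young."""
    required = {"sigma0_kpa", "epsilon0", "delta_rad"}
    missing = required - set(samples.columns)
    if missing:
        raise ParameterError(f"missing columns: {sorted(missing)}")
    out = samples.copy()
    rows = [
        MechanicalSample(r.sigma0_kpa, r.epsilon0, r.delta_rad)
        for r in samples.itertuples()
    ]
    out["E_storage"] = [storage_modulus(s) for s in rows]
    out["E_loss"] = [loss_modulus(s) for s in rows]
    out["E_young"] = [young_modulus(s) for s in rows]
    return out
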