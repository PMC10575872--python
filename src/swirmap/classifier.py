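"""Composite-specific SWIR thresholding and inundation frequency.

Water absorbs strongly in the short-wave infrared, so inundated pixels sit
at low SWIR reflectance.  For each annual composite the threshold is placed
between the median reflectance of the permanent-wet reference pixels and
the median of the permanent-dry reference pixels:

    SWIR_threshold = SWIR_wet + c * (SWIR_dry - SWIR_wet),   c = 0.3

Pixels strictly below the threshold are labelled inundated (1), pixels at
or above it dry (0).  Yearly binary maps are aggregated into a per-pixel
inundation-frequency map (percent of available years classified wet).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from swirmap.compositing import AnnualComposite
from swirmap.synthetic import ReferenceRegions

__all__ = [
    "DEFAULT_COEFFICIENT",
    "NODATA_LABEL",
    "ThresholdRecord",
    "InundationMap",
    "FrequencyMap",
    "DegenerateThresholdError",
    "threshold_from_medians",
    "compute_swir_threshold",
    "classify_inundation",
    "inundation_frequency",
]

#: Interpolation coefficient between the wet and dry reference medians.
#: Inherited from the SWIR-thresholding literature; never varied in the
#: source analysis.
DEFAULT_COEFFICIENT = 0.3

#: uint8 nodata code in inundation-map label grids.
NODATA_LABEL = 255


class DegenerateThresholdError(ValueError):
    """Raised when classifying with a degenerate (dry <= wet) threshold."""


@dataclass(frozen=True)
class ThresholdRecord:
    """One composite's reference medians and derived threshold.

    ``degenerate`` is True iff ``swir_dry <= swir_wet``, i.e. the reference
    regions no longer separate water from land and classifying against the
    threshold would invert the map's meaning.
    """

    year: int
    swir_wet: float
    swir_dry: float
    swir_threshold: float
    degenerate: bool
    coefficient: float = DEFAULT_COEFFICIENT


@dataclass
class InundationMap:
    """Binary wet/dry grid for one year: 1 inundated, 0 dry, 255 nodata."""

    year: int
    labels: np.ndarray
    threshold_used: ThresholdRecord | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape

    @property
    def valid_mask(self) -> np.ndarray:
        return self.labels != NODATA_LABEL

    @property
    def wet_mask(self) -> np.ndarray:
        return self.labels == 1


@dataclass
class FrequencyMap:
    """Per-pixel percent of available years classified inundated (0-100).

    ``n_years_available`` counts the maps with a valid (non-nodata) label at
    each pixel; ``percent`` is NaN where that count is zero, so the 0-100
    contract holds exactly even when some years are nodata at a pixel.
    """

    percent: np.ndarray
    n_years_available: np.ndarray


def threshold_from_medians(
    swir_wet: float, swir_dry: float, coefficient: float = DEFAULT_COEFFICIENT
) -> float:
    """Threshold reflectance from the wet and dry reference medians."""
    return swir_wet + coefficient * (swir_dry - swir_wet)


def compute_swir_threshold(
    composite: AnnualComposite,
    refs: ReferenceRegions,
    coefficient: float = DEFAULT_COEFFICIENT,
) -> ThresholdRecord:
    """Compute the composite-specific threshold from the reference regions.

    Medians are taken over the reference pixels that are valid (non-nodata)
    in this composite; an empty usable wet or dry set is an error naming
    the offending set.
    """
    valid = np.isfinite(composite.swir)
    wet_vals = composite.swir[refs.wet_mask & valid]
    dry_vals = composite.swir[refs.dry_mask & valid]
    if wet_vals.size == 0:
        raise ValueError(
            f"year {composite.year}: no valid pixels in the wet reference"
        )
    if dry_vals.size == 0:
        raise ValueError(
            f"year {composite.year}: no valid pixels in the dry reference"
        )
    swir_wet = float(np.median(wet_vals))
    swir_dry = float(np.median(dry_vals))
    return ThresholdRecord(
        year=composite.year,
        swir_wet=swir_wet,
        swir_dry=swir_dry,
        swir_threshold=threshold_from_medians(swir_wet, swir_dry, coefficient),
        degenerate=swir_dry <= swir_wet,
        coefficient=coefficient,
    )


def classify_inundation(
    composite: AnnualComposite,
    thr: ThresholdRecord,
    allow_degenerate: bool = False,
) -> InundationMap:
    """Threshold a composite into a binary inundation map.

    Label 1 where SWIR < threshold, 0 where SWIR >= threshold (a pixel
    exactly at the threshold is dry -- the conservative reading), nodata
    where the composite is nodata.  A degenerate threshold is refused
    unless ``allow_degenerate`` is set.
    """
    if thr.degenerate and not allow_degenerate:
        raise DegenerateThresholdError(
            f"year {thr.year}: dry reference median ({thr.swir_dry}) <= wet "
            f"reference median ({thr.swir_wet}); refusing to classify"
        )
    labels = np.full(composite.shape, NODATA_LABEL, dtype=np.uint8)
    valid = np.isfinite(composite.swir)
    labels[valid] = (composite.swir[valid] < thr.swir_threshold).astype(np.uint8)
    return InundationMap(year=composite.year, labels=labels, threshold_used=thr)


def inundation_frequency(maps: Sequence[InundationMap]) -> FrequencyMap:
    """Aggregate yearly maps into a percent-of-years-inundated grid.

    Per pixel: 100 x (#maps labelling it wet) / (#maps with a valid label
    there); NaN where no map has a valid label.
    """
    if not maps:
        raise ValueError("need at least one inundation map")
    shape = maps[0].shape
    for m in maps:
        if m.shape != shape:
            raise ValueError("inundation maps do not share geometry")
    wet = np.zeros(shape, dtype=np.int64)
    avail = np.zeros(shape, dtype=np.int64)
    for m in maps:
        valid = m.valid_mask
        avail += valid
        wet += m.wet_mask
    with np.errstate(invalid="ignore", divide="ignore"):
        percent = np.where(avail > 0, 100.0 * wet / np.maximum(avail, 1), np.nan)
    return FrequencyMap(percent=percent, n_years_available=avail)
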