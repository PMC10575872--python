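"""Scene masking, gap-filling and annual median compositing.

A :class:`Scene` is one dated satellite observation of a site: a SWIR
reflectance grid (possibly absent -- some archive scenes lack the band), a
QA grid flagging cloud / cloud-shadow pixels, and a boolean validity grid.
The compositing chain is

    apply_cloud_mask -> gap_fill -> build_annual_composite -> filter_composites

i.e. flagged pixels are invalidated, invalidated pixels are filled from the
per-pixel median of temporally adjacent scenes, each year's in-season scenes
are reduced to a per-pixel median composite, and composites that are missing
the SWIR band or retain too much masking are discarded.
"""

from __future__ import annotations

import datetime as _dt
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QA_CLEAR",
    "QA_CLOUD",
    "QA_SHADOW",
    "Scene",
    "AnnualComposite",
    "apply_cloud_mask",
    "gap_fill",
    "build_annual_composite",
    "filter_composites",
    "parse_month_day",
    "DEFAULT_SEASON",
]

# QA grid encoding: anything nonzero is treated as contaminated.
QA_CLEAR = 0
QA_CLOUD = 1
QA_SHADOW = 2

#: June 1 .. September 30 inclusive, the peak-inundation season.
DEFAULT_SEASON = ("06-01", "09-30")

#: Gap-fill candidate window: "a year before or after" the scene date.
GAP_FILL_WINDOW_DAYS = 366


def parse_month_day(md: str) -> tuple[int, int]:
    """Parse ``"MM-DD"`` into an ``(month, day)`` tuple."""
    month, day = md.split("-")
    return int(month), int(day)


@dataclass
class Scene:
    """One dated observation: SWIR grid (or ``None``), QA grid, validity grid.

    Invariant maintained by the operations in this module: ``valid`` is False
    wherever the SWIR band is absent or non-finite, and (after masking)
    wherever QA flags cloud or cloud shadow.
    """

    date: _dt.date
    scene_id: str
    qa: np.ndarray
    swir: np.ndarray | None = None
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.qa = np.asarray(self.qa, dtype=np.uint8)
        if self.swir is not None:
            self.swir = np.asarray(self.swir, dtype=np.float64)
            if self.swir.shape != self.qa.shape:
                raise ValueError(
                    f"scene {self.scene_id}: swir shape {self.swir.shape} "
                    f"!= qa shape {self.qa.shape}"
                )
        if self.valid is None:
            if self.swir is None:
                self.valid = np.zeros(self.qa.shape, dtype=bool)
            else:
                self.valid = np.isfinite(self.swir)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.qa.shape:
            raise ValueError(f"scene {self.scene_id}: valid/qa shape mismatch")

    @property
    def shape(self) -> tuple[int, int]:
        return self.qa.shape

    @property
    def has_swir(self) -> bool:
        return self.swir is not None

    def copy(self) -> "Scene":
        return Scene(
            date=self.date,
            scene_id=self.scene_id,
            qa=self.qa.copy(),
            swir=None if self.swir is None else self.swir.copy(),
            valid=self.valid.copy(),
        )


@dataclass
class AnnualComposite:
    """Per-year median SWIR grid with quality-control metadata.

    ``swir`` uses NaN as nodata; ``masked_fraction`` is the fraction of
    pixels left with no valid value; ``has_swir`` is False iff no
    contributing scene carried the SWIR band at all.
    """

    year: int
    swir: np.ndarray
    masked_fraction: float
    n_scenes: int
    has_swir: bool

    @property
    def shape(self) -> tuple[int, int]:
        return self.swir.shape

    @property
    def nodata_mask(self) -> np.ndarray:
        return ~np.isfinite(self.swir)


def apply_cloud_mask(scene: Scene) -> Scene:
    """Invalidate every pixel whose QA value flags cloud or cloud shadow.

    SWIR values are untouched; only the validity grid changes. Idempotent.
    """
    if scene.qa is None:
        raise ValueError(f"scene {scene.scene_id} has no QA grid")
    out = scene.copy()
    out.valid &= scene.qa == QA_CLEAR
    return out


def gap_fill(scene: Scene, archive: Sequence[Scene]) -> Scene:
    """Fill invalid pixels from the per-pixel median of adjacent scenes.

    For each invalid pixel the candidate pool is that pixel's valid values
    over archive scenes dated within +-366 days of ``scene.date``, the scene
    itself excluded.  Pixels with an empty pool stay invalid; valid pixels
    are never modified, so gap-filling a fully valid scene is the identity.
    """
    for s in archive:
        if s.shape != scene.shape:
            raise ValueError(
                f"archive scene {s.scene_id} shape {s.shape} does not match "
                f"scene {scene.scene_id} shape {scene.shape}"
            )
    if scene.swir is None:
        # Nothing to fill into: the band itself is missing.
        return scene.copy()
    out = scene.copy()
    invalid = ~out.valid
    if not invalid.any():
        return out
    pool = [
        s
        for s in archive
        if s.scene_id != scene.scene_id
        and s.swir is not None
        and abs((s.date - scene.date).days) <= GAP_FILL_WINDOW_DAYS
    ]
    if not pool:
        return out
    stack = np.stack([np.where(s.valid, s.swir, np.nan) for s in pool])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        fill = np.nanmedian(stack, axis=0)
    fillable = invalid & np.isfinite(fill)
    out.swir[fillable] = fill[fillable]
    out.valid |= fillable
    return out


def _in_season(date: _dt.date, year: int, window: tuple[str, str]) -> bool:
    start = parse_month_day(window[0])
    end = parse_month_day(window[1])
    return (
        date.year == year
        and start <= (date.month, date.day) <= end
    )


def build_annual_composite(
    scenes: Sequence[Scene],
    year: int,
    window: tuple[str, str] = DEFAULT_SEASON,
) -> AnnualComposite:
    """Per-pixel median of valid SWIR values over the year's in-season scenes.

    Even-count median is the mean of the two middle values.  Pixels with no
    valid observation are nodata (NaN).  When no in-season scene carries the
    SWIR band, a ``has_swir=False`` composite is returned rather than an
    error so that filtering can report it.
    """
    in_window = [s for s in scenes if _in_season(s.date, year, window)]
    if not in_window:
        raise ValueError(f"no scenes fall inside the {year} season window")
    shape = in_window[0].shape
    contributing = [s for s in in_window if s.swir is not None]
    if not contributing:
        return AnnualComposite(
            year=year,
            swir=np.full(shape, np.nan),
            masked_fraction=1.0,
            n_scenes=0,
            has_swir=False,
        )
    stack = np.stack([np.where(s.valid, s.swir, np.nan) for s in contributing])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        median = np.nanmedian(stack, axis=0)
    masked = ~np.isfinite(median)
    return AnnualComposite(
        year=year,
        swir=median,
        masked_fraction=float(masked.mean()),
        n_scenes=len(contributing),
        has_swir=True,
    )


def filter_composites(
    composites: Sequence[AnnualComposite],
    max_masked_fraction: float = 0.0,
) -> tuple[list[AnnualComposite], pd.DataFrame]:
    """Drop composites missing the SWIR band or exceeding the masking cap.

    The default cap of 0 keeps only composites devoid of masking whatsoever;
    the comparison is strict (``masked_fraction > max_masked_fraction``
    rejects).  Returns the kept composites ordered by year and a rejection
    report with one row per dropped composite.
    """
    kept: list[AnnualComposite] = []
    rows: list[dict] = []
    for comp in composites:
        if not comp.has_swir:
            rows.append(
                {
                    "year": comp.year,
                    "reason": "missing SWIR band",
                    "masked_fraction": comp.masked_fraction,
                    "n_scenes": comp.n_scenes,
                }
            )
        elif comp.masked_fraction > max_masked_fraction:
            rows.append(
                {
                    "year": comp.year,
                    "reason": (
                        f"masked_fraction {comp.masked_fraction:.6f} exceeds "
                        f"{max_masked_fraction:.6f}"
                    ),
                    "masked_fraction": comp.masked_fraction,
                    "n_scenes": comp.n_scenes,
                }
            )
        else:
            kept.append(comp)
    kept.sort(key=lambda c: c.year)
    report = pd.DataFrame(
        rows, columns=["year", "reason", "masked_fraction", "n_scenes"]
    )
    return kept, report
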