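"""Synthetic Landsat-like site generator.

Emulates the statistical structure the inundation analysis assumes, so the
whole chain is testable without any satellite download:

* a circular water body whose true area follows a configurable linear
  interannual trend with multiplicative lognormal noise;
* several scenes per June-September season, wet pixels drawn from a
  low-SWIR normal distribution and dry pixels from a high-SWIR one;
* contiguous cloud/shadow patches flagged in the QA grid;
* occasional scenes missing the SWIR band entirely (a known defect of the
  older archive);
* "permanent wet" / "permanent dry" reference regions derived from the
  truth, and validation labels with optional flip noise standing in for
  photo-interpretation error.

Every operation is a pure function of its inputs and the configured seed:
regenerating with the same config reproduces bit-identical output.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import binary_erosion
from skimage.morphology import disk

from swirmap.compositing import (
    DEFAULT_SEASON,
    QA_CLEAR,
    QA_CLOUD,
    Scene,
    parse_month_day,
)

__all__ = [
    "SiteTruthConfig",
    "SyntheticTruth",
    "ReferenceRegions",
    "SiteUnusableError",
    "generate_truth",
    "render_scene_set",
    "derive_reference_regions",
    "reference_labels_at_points",
]


class SiteUnusableError(ValueError):
    """The synthetic site cannot support the analysis (e.g. empty references)."""


@dataclass(frozen=True)
class SiteTruthConfig:
    """Configuration of one synthetic wetland site.

    Defaults emulate the study regime: a 30 m pixel grid observed 1991-2020,
    several scenes per June-September season, water-like SWIR reflectance
    (~0.05) against dry land (~0.25) on the 0-1 surface-reflectance scale.

    Parameters
    ----------
    grid_rows, grid_cols
        Pixel counts of the site grid.
    pixel_size
        Pixel edge length in metres (Landsat SWIR: 30 m).
    year_start, year_end
        Inclusive year range of the simulated record.
    water_center
        (row, col) of the water-body centre; defaults to the grid centre.
    base_radius
        First-year water-body radius in metres; defaults to a quarter of
        the shorter grid dimension.
    area_trend_slope
        Fractional change in true wet area per year (e.g. -0.02 shrinks the
        lake by 2% of its first-year area each year).
    interannual_noise_sd
        Standard deviation of the multiplicative lognormal noise on the
        yearly area (fractional; 0 disables noise).
    scenes_per_season
        Scenes rendered per season, spread evenly over the window.
    season_window
        (start, end) month-day strings, inclusive; default Jun 1 - Sep 30.
    mu_wet, sd_wet, mu_dry, sd_dry
        SWIR reflectance distributions for wet and dry pixels (values are
        truncated to [0, 1]).  Water absorbs strongly in SWIR, so
        ``mu_wet < mu_dry`` is required.
    cloud_fraction
        Expected fraction of pixels flagged cloud/shadow per scene.
    missing_band_prob
        Probability that a scene carries no SWIR grid.
    label_noise_rate
        Probability that a validation reference label is flipped.
    seed
        Root seed; all randomness derives from it.
    """

    grid_rows: int = 100
    grid_cols: int = 100
    pixel_size: float = 30.0
    year_start: int = 1991
    year_end: int = 2020
    water_center: tuple[int, int] | None = None
    base_radius: float | None = None
    area_trend_slope: float = 0.0
    interannual_noise_sd: float = 0.0
    scenes_per_season: int = 4
    season_window: tuple[str, str] = DEFAULT_SEASON
    mu_wet: float = 0.05
    sd_wet: float = 0.02
    mu_dry: float = 0.25
    sd_dry: float = 0.02
    cloud_fraction: float = 0.0
    missing_band_prob: float = 0.0
    label_noise_rate: float = 0.0
    site_id: str = "synthetic-site"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mu_wet >= self.mu_dry:
            raise ValueError(
                f"mu_wet ({self.mu_wet}) must be < mu_dry ({self.mu_dry}): "
                "the classifier assumes water is darker in SWIR"
            )
        if not (0.0 <= self.cloud_fraction < 1.0):
            raise ValueError("cloud_fraction must be in [0, 1)")
        if not (0.0 <= self.missing_band_prob <= 1.0):
            raise ValueError("missing_band_prob must be in [0, 1]")
        if not (0.0 <= self.label_noise_rate < 0.5):
            raise ValueError("label_noise_rate must be in [0, 0.5)")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.scenes_per_season < 1:
            raise ValueError("scenes_per_season must be >= 1")
        if self.year_end < self.year_start:
            raise ValueError("year_end must be >= year_start")
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid must be non-empty")
        if self.interannual_noise_sd < 0:
            raise ValueError("interannual_noise_sd must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.year_start, self.year_end + 1)

    @property
    def center(self) -> tuple[float, float]:
        if self.water_center is not None:
            return (float(self.water_center[0]), float(self.water_center[1]))
        return ((self.grid_rows - 1) / 2.0, (self.grid_cols - 1) / 2.0)

    @property
    def radius_m(self) -> float:
        if self.base_radius is not None:
            return float(self.base_radius)
        return min(self.grid_rows, self.grid_cols) * self.pixel_size / 4.0

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2


@dataclass
class SyntheticTruth:
    """Ground truth of a synthetic site: yearly wet masks and true areas."""

    config: SiteTruthConfig
    masks: np.ndarray  # (n_years, rows, cols) bool
    true_area_km2: np.ndarray  # (n_years,) float

    @property
    def years(self) -> np.ndarray:
        return self.config.years

    def mask_for(self, year: int) -> np.ndarray:
        idx = int(year) - self.config.year_start
        if not (0 <= idx < len(self.masks)):
            raise ValueError(f"year {year} outside truth range")
        return self.masks[idx]


@dataclass
class ReferenceRegions:
    """Disjoint "permanent wet" / "permanent dry" reference pixel masks."""

    wet_mask: np.ndarray
    dry_mask: np.ndarray

    def __post_init__(self) -> None:
        if (self.wet_mask & self.dry_mask).any():
            raise ValueError("wet and dry reference masks overlap")


def _disc_mask(
    rows: int, cols: int, center: tuple[float, float], radius_px: float
) -> np.ndarray:
    rr, cc = np.ogrid[0:rows, 0:cols]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius_px**2


def generate_truth(config: SiteTruthConfig) -> SyntheticTruth:
    """Generate yearly wet masks for the configured site.

    Year ``y`` (index ``k`` from the first year) has true area

        A_k = A_0 * (1 + area_trend_slope * k) * eps_k

    with ``A_0 = pi * base_radius**2`` and ``eps_k`` mean-one lognormal noise
    of standard deviation ``interannual_noise_sd`` (identically 1 when the
    sd is 0).  The area is clipped to the grid, converted back to a radius,
    and rasterised as the set of pixel centres within that radius of the
    water centre.  The recorded true area is the rasterised pixel count
    times the pixel area, so truth bookkeeping matches any downstream
    pixel-counting exactly.
    """
    rng = np.random.default_rng([config.seed, 0])
    years = config.years
    k = np.arange(len(years), dtype=float)
    a0 = math.pi * config.radius_m**2
    areas_m2 = a0 * (1.0 + config.area_trend_slope * k)
    if config.interannual_noise_sd > 0:
        cv = config.interannual_noise_sd
        sigma = math.sqrt(math.log(1.0 + cv**2))
        noise = rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=len(years))
        areas_m2 = areas_m2 * noise
    grid_area = config.grid_rows * config.grid_cols * config.pixel_size**2
    areas_m2 = np.clip(areas_m2, 0.0, grid_area)

    masks = np.zeros((len(years), config.grid_rows, config.grid_cols), dtype=bool)
    for i, area in enumerate(areas_m2):
        radius_px = math.sqrt(area / math.pi) / config.pixel_size
        masks[i] = _disc_mask(
            config.grid_rows, config.grid_cols, config.center, radius_px
        )
    true_area_km2 = masks.sum(axis=(1, 2)) * config.pixel_area_km2
    return SyntheticTruth(config=config, masks=masks, true_area_km2=true_area_km2)


def _season_dates(config: SiteTruthConfig, year: int) -> list[_dt.date]:
    m0, d0 = parse_month_day(config.season_window[0])
    m1, d1 = parse_month_day(config.season_window[1])
    start = _dt.date(year, m0, d0)
    end = _dt.date(year, m1, d1)
    span = (end - start).days
    n = config.scenes_per_season
    if n == 1:
        offsets = [span // 2]
    else:
        offsets = [round(i * span / (n - 1)) for i in range(n)]
    return [start + _dt.timedelta(days=o) for o in offsets]


def _place_cloud_patches(
    rng: np.random.Generator, rows: int, cols: int, fraction: float
) -> np.ndarray:
    """Flag ~``fraction`` of pixels as contiguous square cloud patches.

    Square patches grow from random anchors until the target count is
    reached; the final patch is trimmed (row-major) so the flagged count
    equals ``round(n * fraction)`` exactly.
    """
    qa = np.zeros((rows, cols), dtype=np.uint8)
    target = int(round(rows * cols * fraction))
    if target == 0:
        return qa
    max_side = max(2, min(rows, cols) // 4)
    flagged = 0
    while flagged < target:
        side = int(rng.integers(2, max_side + 1))
        r = int(rng.integers(0, rows))
        c = int(rng.integers(0, cols))
        patch = qa[r : r + side, c : c + side]
        new = np.flatnonzero(patch == QA_CLEAR)
        need = target - flagged
        if len(new) > need:
            new = new[:need]
        patch.flat[new] = QA_CLOUD
        flagged += len(new)
    return qa


def render_scene_set(truth: SyntheticTruth, year: int) -> list[Scene]:
    """Render the season's scenes for one year of a synthetic truth.

    Each pixel draws SWIR from ``Normal(mu_wet, sd_wet)`` if wet in truth,
    ``Normal(mu_dry, sd_dry)`` otherwise, truncated to [0, 1].  Cloud
    patches flag about ``cloud_fraction`` of pixels in the QA grid, and
    with probability ``missing_band_prob`` a scene carries no SWIR grid.
    """
    cfg = truth.config
    wet = truth.mask_for(year)
    scenes: list[Scene] = []
    for i, date in enumerate(_season_dates(cfg, year)):
        rng = np.random.default_rng([cfg.seed, 1, int(year), i])
        qa = _place_cloud_patches(
            rng, cfg.grid_rows, cfg.grid_cols, cfg.cloud_fraction
        )
        scene_id = f"{cfg.site_id}_{date.isoformat()}_{i}"
        if rng.random() < cfg.missing_band_prob:
            scenes.append(Scene(date=date, scene_id=scene_id, qa=qa, swir=None))
            continue
        shape = (cfg.grid_rows, cfg.grid_cols)
        wet_vals = rng.normal(cfg.mu_wet, cfg.sd_wet, size=shape)
        dry_vals = rng.normal(cfg.mu_dry, cfg.sd_dry, size=shape)
        swir = np.clip(np.where(wet, wet_vals, dry_vals), 0.0, 1.0)
        scenes.append(Scene(date=date, scene_id=scene_id, qa=qa, swir=swir))
    return scenes


def derive_reference_regions(
    truth: SyntheticTruth, erosion_margin: int = 0
) -> ReferenceRegions:
    """Permanent wet/dry reference masks from the truth stack.

    The wet reference is the intersection of all yearly wet masks, the dry
    reference the intersection of all yearly dry masks, each morphologically
    eroded by ``erosion_margin`` pixels (a disc footprint) to stand clear of
    the fluctuating shoreline.
    """
    if erosion_margin < 0:
        raise ValueError("erosion_margin must be >= 0")
    wet = truth.masks.all(axis=0)
    dry = (~truth.masks).all(axis=0)
    if erosion_margin > 0:
        footprint = disk(erosion_margin)
        # border_value=1: pixels only erode away from the wet/dry boundary,
        # not from the image edge.
        wet = binary_erosion(wet, structure=footprint, border_value=1)
        dry = binary_erosion(dry, structure=footprint, border_value=1)
    if not wet.any():
        raise SiteUnusableError(
            "permanent-wet reference is empty after erosion; site unusable"
        )
    if not dry.any():
        raise SiteUnusableError(
            "permanent-dry reference is empty after erosion; site unusable"
        )
    return ReferenceRegions(wet_mask=wet, dry_mask=dry)


def reference_labels_at_points(
    truth: SyntheticTruth,
    points: Sequence[tuple[int, int]] | np.ndarray,
    year: int,
    label_noise_rate: float | None = None,
    seed: int | None = None,
) -> np.ndarray:
    """Truth labels (1 wet / 0 dry) at grid points, with optional flip noise.

    Stands in for visual photo-interpretation of reference imagery: each
    label is flipped independently with probability ``label_noise_rate``
    (default taken from the truth's config), reproducibly under ``seed``.
    """
    cfg = truth.config
    if label_noise_rate is None:
        label_noise_rate = cfg.label_noise_rate
    if not (0.0 <= label_noise_rate < 0.5):
        raise ValueError("label_noise_rate must be in [0, 0.5)")
    pts = np.atleast_2d(np.asarray(points, dtype=int))
    if pts.size and (
        (pts[:, 0] < 0).any()
        or (pts[:, 0] >= cfg.grid_rows).any()
        or (pts[:, 1] < 0).any()
        or (pts[:, 1] >= cfg.grid_cols).any()
    ):
        raise ValueError("point outside the site grid")
    mask = truth.mask_for(year)
    labels = mask[pts[:, 0], pts[:, 1]].astype(np.int64)
    if label_noise_rate > 0:
        rng = np.random.default_rng(
            [cfg.seed if seed is None else seed, 2, int(year)]
        )
        flips = rng.random(len(labels)) < label_noise_rate
        labels = labels ^ flips.astype(np.int64)
    return labels
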