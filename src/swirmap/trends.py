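"""Inundated-area time series and Mann-Kendall trend machinery.

The yearly binary maps reduce to an area series (wet-pixel count times the
pixel area; 30 m pixels give 0.0009 km^2 per pixel).  The Mann-Kendall test
then asks whether the series trends monotonically:

    S    = sum_{i<j} sign(x_j - x_i)
    VarS = [ n(n-1)(2n+5) - sum_p t_p (t_p - 1)(2 t_p + 5) ] / 18
    Zc   = (S - 1)/sqrt(VarS)  if S > 0,   0 if S = 0,
           (S + 1)/sqrt(VarS)  if S < 0

with the sum over tie groups of size ``t_p`` and the +-1 continuity
correction under the normal approximation.  A series is classified
significantly increasing/decreasing when |Zc| > 1.96 (two-sided p < 0.05),
otherwise (non-significantly) increasing/decreasing by the sign of Zc, or
no-trend when S = 0.  A lag-1 autocorrelation check annotates each result;
optional lag-1 pre-whitening is available behind a flag.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from swirmap.classifier import InundationMap

__all__ = [
    "Z_CRITICAL",
    "TREND_CLASSES",
    "AreaSeries",
    "MKResult",
    "SiteSummary",
    "Lag1Result",
    "inundated_area_series",
    "mann_kendall",
    "lag1_autocorr",
    "site_summary",
    "covariate_crosstab",
]

logger = logging.getLogger(__name__)

#: Two-sided 5% critical value of the standard normal.
Z_CRITICAL = 1.96

TREND_CLASSES = (
    "significantly_increasing",
    "increasing",
    "no_trend",
    "decreasing",
    "significantly_decreasing",
)

#: Area of one 30 m pixel in km^2.
PIXEL_AREA_30M_KM2 = 0.0009

SMALL_SAMPLE_N = 8


@dataclass
class AreaSeries:
    """Yearly inundated area (km^2) for one site."""

    site_id: str
    years: np.ndarray
    areas: np.ndarray
    pixel_area: float

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.years.shape != self.areas.shape:
            raise ValueError("years and areas must have equal length")
        if len(self.years) and (np.diff(self.years) <= 0).any():
            raise ValueError("years must be strictly increasing")
        if (self.areas < 0).any():
            raise ValueError("areas must be non-negative")

    @property
    def n(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"site_id": self.site_id, "year": self.years, "area_km2": self.areas}
        )


class Lag1Result(NamedTuple):
    r1: float
    flag: bool
    degenerate: bool


@dataclass(frozen=True)
class MKResult:
    """Mann-Kendall statistics and the derived trend class for one series."""

    n: int
    S: int
    varS: float
    Zc: float
    p: float
    r1: float
    r1_flag: bool
    trend_class: str
    prewhitened: bool = False


@dataclass(frozen=True)
class SiteSummary:
    """Distributional summary of a site's yearly inundated areas (km^2)."""

    min: float
    q1: float
    mean: float
    q3: float
    max: float
    year_of_min: int
    year_of_max: int
    max_min_ratio: float  # NaN when min == 0
    ratio_defined: bool


def inundated_area_series(
    maps: Sequence[InundationMap],
    pixel_area: float = PIXEL_AREA_30M_KM2,
    site_id: str = "site",
) -> AreaSeries:
    """Wet-pixel counts times pixel area, one value per map year.

    Nodata pixels contribute zero area; their per-year counts are logged.
    """
    if not maps:
        raise ValueError("need at least one inundation map")
    if pixel_area <= 0:
        raise ValueError("pixel_area must be positive")
    ordered = sorted(maps, key=lambda m: m.year)
    years = []
    areas = []
    for m in ordered:
        n_nodata = int((~m.valid_mask).sum())
        if n_nodata:
            logger.info(
                "site %s year %d: %d nodata pixels contribute zero area",
                site_id,
                m.year,
                n_nodata,
            )
        years.append(m.year)
        areas.append(int(m.wet_mask.sum()) * pixel_area)
    return AreaSeries(
        site_id=site_id,
        years=np.asarray(years),
        areas=np.asarray(areas),
        pixel_area=pixel_area,
    )


def _kendall_s_and_var(x: np.ndarray) -> tuple[int, float]:
    n = len(x)
    diffs = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diffs, k=1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (
        n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))
    ) / 18.0
    return s, float(var_s)


def lag1_autocorr(values: Sequence[float]) -> Lag1Result:
    """Sample lag-1 autocorrelation of the mean-centred series.

    ``flag`` is True when |r1| exceeds the 5% two-sided bound 1.96/sqrt(n),
    i.e. when serial dependence may distort the Mann-Kendall variance.  A
    zero-variance series has no defined autocorrelation; r1 is reported as
    0 with the degenerate flag set.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 values, got {n}")
    centred = x - x.mean()
    denom = float(np.sum(centred**2))
    if denom == 0.0:
        return Lag1Result(r1=0.0, flag=False, degenerate=True)
    r1 = float(np.sum(centred[:-1] * centred[1:]) / denom)
    return Lag1Result(r1=r1, flag=abs(r1) > Z_CRITICAL / np.sqrt(n), degenerate=False)


def _classify_trend(zc: float) -> str:
    if zc > Z_CRITICAL:
        return "significantly_increasing"
    if zc < -Z_CRITICAL:
        return "significantly_decreasing"
    if zc > 0:
        return "increasing"
    if zc < 0:
        return "decreasing"
    return "no_trend"


def mann_kendall(values: Sequence[float], prewhiten: bool = False) -> MKResult:
    """Mann-Kendall monotonic-trend test with tie and continuity corrections.

    Parameters
    ----------
    values
        The time-ordered series (equal spacing assumed).
    prewhiten
        If True, remove the estimated lag-1 autocorrelation
        (``x'_t = x_t - r1 * x_{t-1}``) before computing the statistics.
        Off by default: the autocorrelation check only annotates the result.

    Notes
    -----
    The normal approximation is used for all n >= 3; a warning is emitted
    for n < 8 where it is rough.  A constant series yields S = 0, Zc = 0,
    ``no_trend`` -- not an error.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"Mann-Kendall test needs n >= 3, got n = {n}")
    if n < SMALL_SAMPLE_N:
        warnings.warn(
            f"Mann-Kendall on n = {n} < {SMALL_SAMPLE_N}: the normal "
            "approximation is rough for small samples",
            UserWarning,
            stacklevel=2,
        )
    lag1 = lag1_autocorr(x)
    test_x = x
    prewhitened = False
    if prewhiten and not lag1.degenerate and abs(lag1.r1) > 0:
        test_x = x[1:] - lag1.r1 * x[:-1]
        prewhitened = True

    s, var_s = _kendall_s_and_var(test_x)
    if var_s > 0 and s != 0:
        zc = (s - np.sign(s)) / np.sqrt(var_s)
    else:
        zc = 0.0
    p = float(2.0 * stats.norm.sf(abs(zc)))
    return MKResult(
        n=n,
        S=s,
        varS=var_s,
        Zc=float(zc),
        p=p,
        r1=lag1.r1,
        r1_flag=lag1.flag,
        trend_class=_classify_trend(zc),
        prewhitened=prewhitened,
    )


def site_summary(series: AreaSeries) -> SiteSummary:
    """Min / Q1 / mean / Q3 / max of the area series, with extreme years.

    Quartiles use linear interpolation between order statistics.  The
    max/min ratio is flagged undefined (NaN) when the minimum is zero; ties
    for the extreme years resolve to the earliest year.
    """
    if series.n < 1:
        raise ValueError("empty area series")
    a = series.areas
    q1, q3 = np.percentile(a, [25, 75])
    i_min = int(np.argmin(a))  # argmin/argmax take the first = earliest year
    i_max = int(np.argmax(a))
    amin = float(a[i_min])
    amax = float(a[i_max])
    defined = amin > 0
    return SiteSummary(
        min=amin,
        q1=float(q1),
        mean=float(a.mean()),
        q3=float(q3),
        max=amax,
        year_of_min=int(series.years[i_min]),
        year_of_max=int(series.years[i_max]),
        max_min_ratio=amax / amin if defined else float("nan"),
        ratio_defined=defined,
    )


OVERFLOW_BIN = "overflow"


def covariate_crosstab(
    site_table: pd.DataFrame,
    bin_edges: Sequence[float],
    covariate: str = "covariate",
) -> pd.DataFrame:
    """Count sites per (trend class, covariate bin) with margins.

    Bins are half-open ``[lo, hi)`` over strictly increasing ``bin_edges``;
    a value on an interior edge falls in the upper bin, and values outside
    every bin land in an explicit overflow column.  Rows cover all five
    trend classes plus an ``All`` margin; columns end with an ``All``
    margin.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin_edges must be strictly increasing with >= 2 edges")
    required = {"site_id", "trend_class", covariate}
    missing = required - set(site_table.columns)
    if missing:
        raise ValueError(f"site_table missing columns: {sorted(missing)}")
    bad = set(site_table["trend_class"]) - set(TREND_CLASSES)
    if bad:
        raise ValueError(f"unknown trend classes: {sorted(bad)}")

    labels = [f"[{lo:g}, {hi:g})" for lo, hi in zip(edges[:-1], edges[1:])]
    idx = np.digitize(site_table[covariate].to_numpy(dtype=float), edges)
    col = np.where(
        (idx >= 1) & (idx <= len(labels)),
        np.array(labels + [OVERFLOW_BIN], dtype=object)[
            np.clip(idx - 1, 0, len(labels))
        ],
        OVERFLOW_BIN,
    )
    table = pd.crosstab(
        pd.Categorical(
            site_table["trend_class"], categories=list(TREND_CLASSES)
        ),
        pd.Categorical(col, categories=labels + [OVERFLOW_BIN]),
        dropna=False,
    )
    table.index.name = "trend_class"
    table.columns.name = covariate
    table["All"] = table.sum(axis=1)
    table.loc["All"] = table.sum(axis=0)
    return table
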