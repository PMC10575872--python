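# Methods

## The classification model

The package maps surface water by thresholding short-wave-infrared (SWIR,
Landsat band B7, 30 m) surface reflectance. Open water absorbs SWIR almost
completely, so inundated pixels cluster at low reflectance (~0.02–0.07 on
the 0–1 scale) while soil and vegetation sit far higher (~0.2–0.35). The
threshold is recomputed for every annual composite from two user-supplied
(or, in synthetic mode, truth-derived) reference regions — pixels that are
wet in every year and pixels that are dry in every year:

    SWIR_threshold = SWIR_wet + c (SWIR_dry − SWIR_wet),  c = 0.3 by default

where `SWIR_wet` and `SWIR_dry` are medians over the reference pixels that
are valid in that composite. Recomputing per composite absorbs
sensor-to-sensor and year-to-year radiometric drift: the rule is invariant
to any affine rescaling of reflectance because medians are
affine-equivariant, a property the test suite asserts bit-exactly. The
coefficient 0.3 places the cut nearer the wet mode, which is appropriate
because the wet distribution is much tighter than the dry one; it is
exposed as a config knob but there is no reason to move it in normal use.

Tie-breaking: a pixel exactly at the threshold is labelled dry. The
classification rule only specifies strictly-below as inundated and
strictly-above as dry; labelling the boundary dry is the conservative
completion. A composite whose dry reference median does not exceed its wet
median no longer separates the classes; classifying against it would invert
the map's meaning, so the threshold is flagged degenerate and
classification refuses unless explicitly overridden.

## Compositing and gap-filling

Scenes are first cloud-masked (any nonzero QA code invalidates the pixel;
the reader contract maps whatever QA dialect the source uses onto
clear/cloud/shadow). Invalid pixels are then gap-filled with the median of
that pixel's valid values over scenes dated within ±366 days, the scene
itself excluded. The ±366-day window operationalises "a year before or
after"; candidates are *not* restricted to the same season — with only a
handful of in-season scenes per year the cross-season pool is what makes
filling possible at realistic cloud fractions, and the subsequent per-year
median limits any bias a cross-season value could introduce. Gap-filling
never invalidates a pixel and never touches a valid one, so it is the
identity on clean scenes; masking is idempotent.

The annual composite is the per-pixel median over the year's June 1 –
September 30 scenes (inclusive, configurable), the season of peak monsoon
inundation. Even-count medians are the mean of the two middle values (the
standard convention). Composites missing the SWIR band entirely are
flagged rather than erroring, and the filter drops them along with any
composite whose remaining masked fraction exceeds the cap. The cap
defaults to 0 — only composites devoid of masking pass — but is
configurable because strict filtering discards data heavily when cloud
cover is high; the demo configuration uses 0.01.

## Trend machinery

Yearly inundated area is the wet-pixel count times the pixel area
(0.0009 km² at 30 m); nodata pixels contribute zero and are logged. The
Mann–Kendall test uses

    S    = Σ_{i<j} sign(x_j − x_i)
    VarS = [n(n−1)(2n+5) − Σ_p t_p(t_p−1)(2t_p+5)] / 18
    Zc   = (S ∓ 1)/√VarS   (continuity correction; Zc = 0 when S = 0)

with the tie sum over groups of equal values, and a two-sided normal
p-value. Both the tie correction and the continuity correction are applied
— both are standard, and with areas quantised to whole pixels ties do
occur. A consequence of the continuity correction is that |S| = 1 also
maps to Zc = 0. Series are classified significantly increasing/decreasing
at |Zc| > 1.96 (p < 0.05), otherwise by the sign of Zc, or no-trend at
S = 0. The normal approximation is used for all n ≥ 3 with a warning below
n = 8; exact small-sample tables are out of scope.

The test runs on the years that survived composite filtering, and reports
n; the verdict is not extrapolated to unobserved years. A lag-1
autocorrelation check (flag at |r1| > 1.96/√n) annotates every result
because serial dependence inflates the false-positive rate of the test;
by default it does not modify the statistic. An optional flag applies
plain lag-1 pre-whitening (x_t − r1·x_{t−1}) before testing — plain rather
than trend-free pre-whitening, since the latter requires a Sen's-slope
detrend that is deliberately out of scope. Pre-whitening with a
trend-inflated r1 estimate is known to sap power, which is why it is off
by default.

Site summaries use linearly interpolated quartiles (the common default in
scientific software), break extreme-year ties toward the earliest year,
and flag the max/min area ratio undefined (NaN, never infinity) when the
minimum is zero. The covariate cross-tab bins sites into half-open
[lo, hi) ranges per trend class — a value on an interior edge goes to the
upper bin, values outside every bin to an explicit overflow column.

## Accuracy assessment

Validation draws `n_years = 5` map years uniformly without replacement and
`n_points_per_year = 50` positions uniformly over each chosen map's valid
pixels (250 points per site at the defaults), fully seeded. Sampling valid
pixels only keeps exactly 50 usable points per year; nodata locations are
never drawn. The 2×2 error matrix is oriented rows = predicted,
columns = reference, which the producer's-by-column / user's-by-row
formulas imply; every output header states the orientation. A class with a
zero column (or row) total yields an undefined producer's (user's)
accuracy reported as NaN, never 0. Swapping the two label roles transposes
the matrix and exchanges producer's with user's accuracies while leaving
overall accuracy unchanged — asserted exhaustively over all count grids
with total ≤ 20.

## The synthetic generator

Synthetic sites exist so that every stage can be tested against a known
truth. The water body is a disc: per-pixel thresholding is blind to shape,
so a disc exercises everything a realistic shoreline would while keeping
the analytic area A = πr² available as an oracle. Year k's true area is
A₀(1 + slope·k), perturbed by mean-one multiplicative lognormal noise
(lognormal keeps areas positive), clipped to the grid, and rasterised as
the pixel centres within the implied radius; the recorded truth area is
the rasterised count × pixel area so bookkeeping matches any downstream
pixel count exactly. Reference regions are the intersections of the yearly
wet (resp. dry) masks, eroded by a configurable pixel margin with the
image border treated as foreground; empty references raise a
site-unusable error.

Scenes draw wet pixels from Normal(μ_wet = 0.05, σ = 0.02) and dry pixels
from Normal(μ_dry = 0.25, σ = 0.02), truncated to [0, 1] — centres and
spreads chosen as typical SWIR surface reflectance for open water versus
bare soil/vegetated land, with the spread small enough that the two modes
overlap only in the far tails, which is the regime the thresholding method
assumes (its real-world failure modes — vegetation-ringed lakes, shadows,
mixed pixels — narrow exactly this gap). Defaults simulate 1991–2020 with
four scenes per season spread evenly over the window, a conservative count
of usable acquisitions per season. Clouds are contiguous square patches
grown from random anchors until the flagged count reaches
round(n·cloud_fraction) exactly (the last patch is trimmed); contiguity
matters because it produces the multi-scene overlaps that stress
gap-filling harder than independent per-pixel flags would. Scenes lose
their SWIR band entirely with probability `missing_band_prob`, emulating
the early-archive composites that lacked B7. Validation labels are truth
values flipped independently with probability `label_noise_rate` — a free
parameter standing in for photo-interpretation error, for which no
quantitative model exists.

What the generator does *not* emulate: radiative-transfer effects, sensor
geometry, terrain shadows, mixed-pixel spectra, spatially correlated
reflectance noise, or realistic shoreline geometry. Passing tests
therefore demonstrate that the pipeline's logic is correct and calibrated
under its own assumptions, not that those assumptions hold for any
particular real wetland.

## Numerical and I/O choices

Composites use NaN as nodata; label grids use uint8 with 255 as nodata.
Inundation frequency uses per-pixel denominators (#years with a valid
label at that pixel), keeping the 0–100 contract exact when some years are
nodata. All randomness flows from integer seeds through
`numpy.random.default_rng` with distinct child keys per purpose, so every
operation is a pure function of (inputs, seed) and stage re-runs are
bit-identical. Rasters are written as single-band TIFF with a JSON
metadata document (band, date, nodata, pixel size, origin, declared
integer scale/offset for real surface-reflectance products) in the image
description tag; reference regions also export as GeoJSON polygon unions
of their pixel squares. Numeric CSV intermediates are written at %.17g and
read with round-trip float parsing so file-based stage resumption
reproduces in-memory results exactly.

## Problem sizes in the test suite

End-to-end recovery tests run a 200×200-pixel site over 30 years with 4
scenes per season (clean, and with 30 % cloud cover); calibration tests
use 500 null replicates and 200 power replicates at n = 30; oracle
equivalence uses 200 random series of length 3–40. These sizes give the
binomial/sampling bounds in the assertions comfortable margins while the
whole suite runs in seconds.

## Known limitations

* Binary wet/dry only — no wetland typing, spectral indices, or sub-pixel
  water fractions.
* No Sen's slope, seasonal Mann–Kendall, or change-point detection; the
  trend output is a monotonicity verdict, not a magnitude.
* No kappa or area-adjusted accuracy estimators.
* The QA reader contract is three-way (clear/cloud/shadow); decoding
  specific Landsat collection bit-flag dialects is the caller's concern.
* Written TIFFs carry their geotransform in JSON metadata rather than
  GeoTIFF geo-keys, so GIS software will read them as plain rasters.
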