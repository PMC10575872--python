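# swirmap

Long-term wetland inundation mapping from short-wave-infrared (SWIR)
reflectance, for ecologists and remote-sensing practitioners who need to
turn a multi-decade stack of cloudy satellite scenes into defensible
statements like *"this wetland's inundated area has declined significantly
since 1991"*.

Water absorbs strongly in the SWIR band, so inundated pixels are dark.
`swirmap` implements the classic band-thresholding chain around that fact:

1. **Cloud masking & gap-filling** — pixels flagged cloud/cloud-shadow in a
   scene's QA grid are invalidated, then filled with the per-pixel median of
   the same pixel's valid observations from scenes dated within ±366 days.
2. **Annual median composites** — all scenes from the June–September peak
   season of each year are reduced to one per-pixel-median SWIR grid;
   composites missing the SWIR band or retaining masked pixels beyond a cap
   are discarded with a reasoned rejection report.
3. **Composite-specific thresholding** — with `SWIR_wet` and `SWIR_dry` the
   median reflectance of digitised permanent-wet and permanent-dry
   reference regions in that composite,

   ```
   SWIR_threshold = SWIR_wet + 0.3 (SWIR_dry − SWIR_wet)
   ```

   pixels below the threshold are labelled inundated (1), the rest dry (0).
4. **Inundation frequency** — per pixel, the percentage of available years
   labelled wet (0–100).
5. **Trend analysis** — yearly wet-pixel counts × pixel area (0.0009 km²
   for 30 m pixels) form an area series tested with the Mann–Kendall
   statistic `S = Σ_{i<j} sign(x_j − x_i)`, tie-corrected variance,
   continuity correction, and a lag-1 autocorrelation check; |Z_c| > 1.96
   (two-sided p < 0.05) marks a significant trend.
6. **Accuracy assessment** — 50 random points on each of 5 random years
   (250 per site), predicted labels crossed against reference labels in a
   2×2 error matrix with overall, producer's and user's accuracies.

Because real 30-year Landsat archives are enormous, the package ships a
first-class **synthetic site generator**: a circular water body with a
configurable interannual area trend and noise, Gaussian wet/dry SWIR
distributions, contiguous cloud patches, occasionally missing SWIR bands,
and noisy validation labels. Every stage of the pipeline is exercised and
validated end-to-end against this known truth.

## Worked example

Write a site config (flat `key = value` text), then run the whole chain:

```bash
swirmap run-all --config demo.cfg --out-dir demo-out/
```

with `demo.cfg` describing an 80×80-pixel site observed 1991–2020, four
scenes per season, a −2 %/yr area trend, 5 % interannual noise and 15 %
cloud cover per scene:

```ini
grid_rows = 80
grid_cols = 80
year_start = 1991
year_end = 2020
area_trend_slope = -0.02
interannual_noise_sd = 0.05
cloud_fraction = 0.15
site_id = demo-wetland
seed = 7
max_masked_fraction = 0.01
```

Output:

```
site demo-wetland: 30 composites, trend significantly_decreasing (Zc=-7.177), overall accuracy 99.6%
report -> demo-out/report.json
```

The report says the injected decline was recovered: all 30 yearly
composites survived filtering, the Mann–Kendall statistic on the area
series is S = −403 with Z_c = −7.18 (p ≈ 7×10⁻¹³, far past the 1.96
cutoff), the inundated area fell from a 1.14 km² maximum in 1991 to a
0.49 km² minimum in 2017 (max/min ratio 2.34), and 249 of the 250
validation points matched the truth (overall accuracy 99.6 %, wet-class
producer's accuracy 96.2 %).

Each stage is also its own subcommand (`simulate`, `composite`,
`classify`, `frequency`, `trend`, `validate`) operating on the file
intermediates under `--out-dir`, so any stage can be re-run alone;
`batch` runs many sites and tallies their trend classes. The same
operations are importable from Python (`swirmap.mann_kendall`,
`swirmap.compute_swir_threshold`, ...).

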