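"""Site- and batch-level orchestration with file-based, resumable stages.

A site run executes the whole chain

    simulate -> composite -> classify -> frequency -> trend -> validate

writing every intermediate under the site's output directory, so any stage
can be re-run from the files the previous stage left behind.  Each stage is
deterministic under the configured seed; deleting downstream intermediates
and re-running reproduces them exactly.  A batch run executes independent
site runs and tallies trend classes and mean overall accuracy; one broken
site is reported, not fatal.
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

from swirmap import accuracy as _accuracy
from swirmap import classifier as _classifier
from swirmap import compositing as _compositing
from swirmap import rasters as _rasters
from swirmap import synthetic as _synthetic
from swirmap import trends as _trends
from swirmap.classifier import NODATA_LABEL, InundationMap
from swirmap.compositing import AnnualComposite, Scene
from swirmap.synthetic import SiteTruthConfig

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "SiteReport",
    "BatchSummary",
    "run_site",
    "run_batch",
    "stage_simulate",
    "stage_composite",
    "stage_classify",
    "stage_frequency",
    "stage_trend",
    "stage_validate",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "composite", "classify", "frequency", "trend", "validate")


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name (and year when applicable)."""

    def __init__(self, stage: str, message: str, year: int | None = None):
        self.stage = stage
        self.year = year
        where = f"stage {stage}" + (f", year {year}" if year is not None else "")
        super().__init__(f"{where}: {message}")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a site run needs: the truth config plus stage knobs."""

    truth: SiteTruthConfig
    max_masked_fraction: float = 0.0
    coefficient: float = _classifier.DEFAULT_COEFFICIENT
    erosion_margin: int = 1
    gap_fill: bool = True
    n_validation_years: int = 5
    n_points_per_year: int = 50

    @property
    def site_id(self) -> str:
        return self.truth.site_id

    def to_flat_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {}
        for f in dataclasses.fields(self.truth):
            d[f.name] = getattr(self.truth, f.name)
        for f in dataclasses.fields(self):
            if f.name != "truth":
                d[f.name] = getattr(self, f.name)
        return d

    @classmethod
    def from_flat_dict(cls, values: dict[str, str | Any]) -> "PipelineConfig":
        truth_kwargs: dict[str, Any] = {}
        own_kwargs: dict[str, Any] = {}
        truth_fields = {f.name: f for f in dataclasses.fields(SiteTruthConfig)}
        own_fields = {
            f.name: f for f in dataclasses.fields(cls) if f.name != "truth"
        }
        for key, raw in values.items():
            if key in truth_fields:
                truth_kwargs[key] = _coerce(key, raw)
            elif key in own_fields:
                own_kwargs[key] = _coerce(key, raw)
            else:
                raise ValueError(f"unknown config key: {key}")
        return cls(truth=SiteTruthConfig(**truth_kwargs), **own_kwargs)

    def config_hash(self) -> str:
        text = json.dumps(
            {k: _jsonable(v) for k, v in sorted(self.to_flat_dict().items())}
        )
        return hashlib.sha256(text.encode()).hexdigest()[:16]


_BOOL_KEYS = {"gap_fill"}
_INT_KEYS = {
    "grid_rows",
    "grid_cols",
    "year_start",
    "year_end",
    "scenes_per_season",
    "seed",
    "erosion_margin",
    "n_validation_years",
    "n_points_per_year",
}
_STR_KEYS = {"site_id"}
_TUPLE_KEYS = {"water_center", "season_window"}


def _coerce(key: str, raw: Any) -> Any:
    if not isinstance(raw, str):
        return raw
    if raw.lower() in ("none", ""):
        return None
    if key in _TUPLE_KEYS:
        parts = [p.strip() for p in raw.split(",")]
        if key == "water_center":
            return (int(parts[0]), int(parts[1]))
        return tuple(parts)
    if key in _BOOL_KEYS:
        return raw.lower() in ("1", "true", "yes", "on")
    if key in _INT_KEYS:
        return int(raw)
    if key in _STR_KEYS:
        return raw
    return float(raw)


def _jsonable(v: Any) -> Any:
    if isinstance(v, tuple):
        return list(v)
    return v


@dataclass
class SiteReport:
    """Everything a site run produced, serialisable to JSON."""

    site_id: str
    n_composites_kept: int
    n_composites_rejected: int
    thresholds: list[dict]
    frequency_map_path: str | None
    years: list[int]
    areas_km2: list[float]
    mk: dict
    summary: dict
    error_matrix: dict
    config_hash: str
    seed: int
    created: str = field(default_factory=lambda: _dt.datetime.now().isoformat())

    def payload(self) -> dict:
        """The scientific content, excluding run metadata timestamps."""
        d = self.to_dict()
        d.pop("created")
        d.pop("frequency_map_path")
        return d

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(json.dumps(self.to_dict(), indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "SiteReport":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class BatchSummary:
    """Per-batch tally of trend classes plus mean overall accuracy."""

    n_sites: int
    trend_tally: dict[str, int]
    mean_overall_accuracy: float
    site_table: pd.DataFrame
    failures: dict[str, str]


# ---------------------------------------------------------------------------
# File-based stages.  Each reads only what earlier stages wrote.
# ---------------------------------------------------------------------------


def _scene_paths(out_dir: Path) -> Path:
    return out_dir / "scenes"


def stage_simulate(config: PipelineConfig, out_dir: str | Path) -> None:
    """Generate truth, scenes and reference regions; write them all."""
    out = Path(out_dir)
    cfg = config.truth
    try:
        truth = _synthetic.generate_truth(cfg)
        refs = _synthetic.derive_reference_regions(truth, config.erosion_margin)
    except (ValueError, _synthetic.SiteUnusableError) as exc:
        raise PipelineStageError("simulate", str(exc)) from exc

    _rasters.write_config(out / "config.txt", config.to_flat_dict())
    truth_dir = out / "truth"
    for year, mask in zip(truth.years, truth.masks):
        _rasters.write_raster(
            truth_dir / f"truth_{year}.tif",
            mask.astype(np.uint8),
            pixel_size=cfg.pixel_size,
            band="truth",
            date=f"{year}",
        )
    pd.DataFrame({"year": truth.years, "true_area_km2": truth.true_area_km2}).to_csv(
        truth_dir / "true_areas.csv", index=False
    )
    _rasters.write_raster(
        out / "refs" / "wet.tif",
        refs.wet_mask.astype(np.uint8),
        pixel_size=cfg.pixel_size,
        band="reference_wet",
    )
    _rasters.write_raster(
        out / "refs" / "dry.tif",
        refs.dry_mask.astype(np.uint8),
        pixel_size=cfg.pixel_size,
        band="reference_dry",
    )
    _rasters.mask_to_geojson(
        out / "refs" / "wet.geojson",
        refs.wet_mask,
        pixel_size=cfg.pixel_size,
        properties={"region": "permanent_wet", "site_id": cfg.site_id},
    )
    _rasters.mask_to_geojson(
        out / "refs" / "dry.geojson",
        refs.dry_mask,
        pixel_size=cfg.pixel_size,
        properties={"region": "permanent_dry", "site_id": cfg.site_id},
    )
    scenes_dir = _scene_paths(out)
    for year in truth.years:
        for scene in _synthetic.render_scene_set(truth, int(year)):
            stem = scene.scene_id
            _rasters.write_raster(
                scenes_dir / f"{stem}_qa.tif",
                scene.qa,
                pixel_size=cfg.pixel_size,
                band="QA",
                date=scene.date,
                extra={"scene_id": scene.scene_id},
            )
            if scene.swir is not None:
                _rasters.write_raster(
                    scenes_dir / f"{stem}_swir.tif",
                    scene.swir.astype(np.float32),
                    nodata=float("nan"),
                    pixel_size=cfg.pixel_size,
                    band="SWIR",
                    date=scene.date,
                    extra={"scene_id": scene.scene_id},
                )


def _load_scenes(out_dir: Path) -> list[Scene]:
    scenes_dir = _scene_paths(out_dir)
    qa_files = sorted(scenes_dir.glob("*_qa.tif"))
    if not qa_files:
        raise PipelineStageError("composite", f"no scenes found in {scenes_dir}")
    scenes = []
    for qa_path in qa_files:
        qa, meta = _rasters.read_raster(qa_path)
        date = _dt.date.fromisoformat(meta["date"])
        scene_id = meta["scene_id"]
        swir_path = scenes_dir / f"{scene_id}_swir.tif"
        swir = None
        if swir_path.exists():
            swir, _ = _rasters.read_raster(swir_path)
            swir = np.asarray(swir, dtype=np.float64)
        scenes.append(Scene(date=date, scene_id=scene_id, qa=qa, swir=swir))
    return scenes


def stage_composite(config: PipelineConfig, out_dir: str | Path) -> None:
    """Mask, gap-fill and composite the stored scenes; filter the result."""
    out = Path(out_dir)
    cfg = config.truth
    scenes = _load_scenes(out)
    masked = [_compositing.apply_cloud_mask(s) for s in scenes]
    if config.gap_fill:
        masked = [_compositing.gap_fill(s, masked) for s in masked]
    composites = []
    for year in cfg.years:
        composites.append(
            _compositing.build_annual_composite(
                masked, int(year), window=cfg.season_window
            )
        )
    kept, report = _compositing.filter_composites(
        composites, config.max_masked_fraction
    )
    if not kept:
        raise PipelineStageError(
            "composite",
            f"zero usable composites after filtering ({len(report)} rejected)",
        )
    comp_dir = out / "composites"
    for comp in kept:
        _rasters.write_raster(
            comp_dir / f"composite_{comp.year}.tif",
            comp.swir.astype(np.float32),
            nodata=float("nan"),
            pixel_size=cfg.pixel_size,
            band="SWIR_median",
            date=f"{comp.year}",
            extra={
                "year": comp.year,
                "masked_fraction": comp.masked_fraction,
                "n_scenes": comp.n_scenes,
            },
        )
    report.to_csv(comp_dir / "rejections.csv", index=False)


def _load_composites(out_dir: Path) -> list[AnnualComposite]:
    comp_dir = Path(out_dir) / "composites"
    files = sorted(comp_dir.glob("composite_*.tif"))
    if not files:
        raise PipelineStageError("classify", f"no composites found in {comp_dir}")
    composites = []
    for path in files:
        swir, meta = _rasters.read_raster(path)
        composites.append(
            AnnualComposite(
                year=int(meta["year"]),
                swir=np.asarray(swir, dtype=np.float64),
                masked_fraction=float(meta["masked_fraction"]),
                n_scenes=int(meta["n_scenes"]),
                has_swir=True,
            )
        )
    return composites


def _load_refs(out_dir: Path) -> _synthetic.ReferenceRegions:
    wet, _ = _rasters.read_raster(Path(out_dir) / "refs" / "wet.tif")
    dry, _ = _rasters.read_raster(Path(out_dir) / "refs" / "dry.tif")
    return _synthetic.ReferenceRegions(
        wet_mask=wet.astype(bool), dry_mask=dry.astype(bool)
    )


def stage_classify(config: PipelineConfig, out_dir: str | Path) -> None:
    """Threshold each kept composite into an inundation map."""
    out = Path(out_dir)
    composites = _load_composites(out)
    refs = _load_refs(out)
    records = []
    maps_dir = out / "maps"
    for comp in composites:
        try:
            thr = _classifier.compute_swir_threshold(
                comp, refs, coefficient=config.coefficient
            )
            imap = _classifier.classify_inundation(comp, thr)
        except ValueError as exc:
            raise PipelineStageError("classify", str(exc), year=comp.year) from exc
        records.append(dataclasses.asdict(thr))
        _rasters.write_raster(
            maps_dir / f"inundation_{comp.year}.tif",
            imap.labels,
            nodata=NODATA_LABEL,
            pixel_size=config.truth.pixel_size,
            band="inundation",
            date=f"{comp.year}",
            extra={"year": comp.year, "threshold": thr.swir_threshold},
        )
    pd.DataFrame.from_records(records)[
        ["year", "swir_wet", "swir_dry", "swir_threshold", "degenerate"]
    ].to_csv(out / "thresholds.csv", index=False, float_format="%.17g")


def _load_maps(out_dir: Path, stage: str) -> list[InundationMap]:
    maps_dir = Path(out_dir) / "maps"
    files = sorted(maps_dir.glob("inundation_*.tif"))
    if not files:
        raise PipelineStageError(stage, f"no inundation maps found in {maps_dir}")
    maps = []
    for path in files:
        labels, meta = _rasters.read_raster(path)
        maps.append(
            InundationMap(year=int(meta["year"]), labels=labels.astype(np.uint8))
        )
    return maps


def stage_frequency(config: PipelineConfig, out_dir: str | Path) -> None:
    """Aggregate the yearly maps into the inundation-frequency raster."""
    out = Path(out_dir)
    maps = _load_maps(out, "frequency")
    freq = _classifier.inundation_frequency(maps)
    _rasters.write_raster(
        out / "frequency.tif",
        freq.percent.astype(np.float32),
        nodata=float("nan"),
        pixel_size=config.truth.pixel_size,
        band="inundation_frequency_percent",
    )
    _rasters.write_raster(
        out / "frequency_n_years.tif",
        freq.n_years_available.astype(np.int32),
        pixel_size=config.truth.pixel_size,
        band="n_years_available",
    )


def stage_trend(config: PipelineConfig, out_dir: str | Path) -> None:
    """Area series, Mann-Kendall result and distributional summary."""
    out = Path(out_dir)
    maps = _load_maps(out, "trend")
    series = _trends.inundated_area_series(
        maps,
        pixel_area=config.truth.pixel_area_km2,
        site_id=config.site_id,
    )
    series.to_frame().to_csv(out / "areas.csv", index=False, float_format="%.17g")
    mk = _trends.mann_kendall(series.areas)
    summary = _trends.site_summary(series)
    row = {
        "site_id": config.site_id,
        "n": mk.n,
        "S": mk.S,
        "varS": mk.varS,
        "Zc": mk.Zc,
        "p": mk.p,
        "r1": mk.r1,
        "r1_flag": mk.r1_flag,
        "trend_class": mk.trend_class,
    }
    row.update(
        {
            "area_min_km2": summary.min,
            "area_q1_km2": summary.q1,
            "area_mean_km2": summary.mean,
            "area_q3_km2": summary.q3,
            "area_max_km2": summary.max,
            "year_of_min": summary.year_of_min,
            "year_of_max": summary.year_of_max,
            "max_min_ratio": summary.max_min_ratio,
        }
    )
    pd.DataFrame([row]).to_csv(out / "trend.csv", index=False, float_format="%.17g")


def stage_validate(config: PipelineConfig, out_dir: str | Path) -> None:
    """Sample validation points, attach truth labels, build the error matrix."""
    out = Path(out_dir)
    cfg = config.truth
    maps = _load_maps(out, "validate")
    try:
        points = _accuracy.sample_validation_points(
            maps,
            n_years=config.n_validation_years,
            n_points_per_year=config.n_points_per_year,
            seed=cfg.seed,
            site_id=cfg.site_id,
        )
        points = _accuracy.extract_predicted_labels(maps, points)
    except ValueError as exc:
        raise PipelineStageError("validate", str(exc)) from exc
    truth = _synthetic.generate_truth(cfg)
    refs = []
    for year, group in points.groupby("year"):
        labels = _synthetic.reference_labels_at_points(
            truth,
            group[["row", "col"]].to_numpy(),
            int(year),
            label_noise_rate=cfg.label_noise_rate,
        )
        refs.append(pd.Series(labels, index=group.index))
    points["reference"] = pd.concat(refs).sort_index()
    val_dir = out / "validation"
    val_dir.mkdir(parents=True, exist_ok=True)
    points.to_csv(val_dir / "points.csv", index=False)
    matrix = _accuracy.build_error_matrix(points)
    (val_dir / "error_matrix.json").write_text(
        json.dumps(matrix.to_dict(), indent=2)
    )


def run_site(config: PipelineConfig, out_dir: str | Path) -> SiteReport:
    """Execute every stage for one site and assemble the report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_simulate(config, out)
    stage_composite(config, out)
    stage_classify(config, out)
    stage_frequency(config, out)
    stage_trend(config, out)
    stage_validate(config, out)

    thresholds = pd.read_csv(out / "thresholds.csv").to_dict("records")
    rejections = pd.read_csv(out / "composites" / "rejections.csv")
    trend_row = pd.read_csv(out / "trend.csv", float_precision="round_trip").iloc[0].to_dict()
    areas = pd.read_csv(out / "areas.csv", float_precision="round_trip")
    matrix = json.loads((out / "validation" / "error_matrix.json").read_text())
    mk_keys = ["n", "S", "varS", "Zc", "p", "r1", "r1_flag", "trend_class"]
    summary_keys = [
        "area_min_km2",
        "area_q1_km2",
        "area_mean_km2",
        "area_q3_km2",
        "area_max_km2",
        "year_of_min",
        "year_of_max",
        "max_min_ratio",
    ]
    report = SiteReport(
        site_id=config.site_id,
        n_composites_kept=len(thresholds),
        n_composites_rejected=len(rejections),
        thresholds=thresholds,
        frequency_map_path=str(out / "frequency.tif"),
        years=[int(y) for y in areas["year"]],
        areas_km2=[float(a) for a in areas["area_km2"]],
        mk={k: _to_plain(trend_row[k]) for k in mk_keys},
        summary={k: _to_plain(trend_row[k]) for k in summary_keys},
        error_matrix=matrix,
        config_hash=config.config_hash(),
        seed=config.truth.seed,
    )
    report.to_json(out / "report.json")
    return report


def _to_plain(v: Any) -> Any:
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    return v


def run_batch(
    configs: Sequence[PipelineConfig], out_dir: str | Path
) -> BatchSummary:
    """Run independent site analyses and summarise the batch.

    A failing site is recorded in ``failures`` and does not abort the rest;
    the batch errors out only if every site fails.
    """
    if not configs:
        raise ValueError("batch needs at least one site config")
    out = Path(out_dir)
    reports: list[SiteReport] = []
    failures: dict[str, str] = {}
    for config in configs:
        site_out = out / config.site_id
        try:
            reports.append(run_site(config, site_out))
        except Exception as exc:  # noqa: BLE001 -- isolate per-site failures
            logger.warning("site %s failed: %s", config.site_id, exc)
            failures[config.site_id] = str(exc)
    if not reports:
        raise RuntimeError(f"all {len(configs)} sites failed: {failures}")
    tally = {c: 0 for c in _trends.TREND_CLASSES}
    rows = []
    for rep in reports:
        tally[rep.mk["trend_class"]] += 1
        rows.append(
            {
                "site_id": rep.site_id,
                "n_composites": rep.n_composites_kept,
                "Zc": rep.mk["Zc"],
                "p": rep.mk["p"],
                "trend_class": rep.mk["trend_class"],
                "overall_accuracy": rep.error_matrix["overall_accuracy"],
            }
        )
    table = pd.DataFrame(rows)
    summary = BatchSummary(
        n_sites=len(reports),
        trend_tally=tally,
        mean_overall_accuracy=float(table["overall_accuracy"].mean()),
        site_table=table,
        failures=failures,
    )
    table.to_csv(out / "batch_sites.csv", index=False)
    (out / "batch_summary.json").write_text(
        json.dumps(
            {
                "n_sites": summary.n_sites,
                "trend_tally": summary.trend_tally,
                "mean_overall_accuracy": summary.mean_overall_accuracy,
                "failures": summary.failures,
            },
            indent=2,
        )
    )
    return summary
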