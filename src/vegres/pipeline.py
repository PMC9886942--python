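"""End-to-end workflow: simulate -> preprocess -> resilience ->
perturbations -> climate -> relate.

Each stage reads its inputs from, and writes its outputs to, a run
directory, so stages are individually re-runnable from intermediate
files. Filter counts (pixels masked, candidates detected, KS-rejected,
R^2-rejected) are logged at every step, and the resolved configuration
is written alongside the outputs. A fixed seed yields byte-identical
tables.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .climate import climate_metrics
from .preprocess import despike, landcover_mask, stl_residual
from .recovery import find_recovery_events
from .relations import RelateConfig, relate, results_to_frame
from .resilience import estimate_resilience
from .series import PrecipSeries
from .synthetic import LandscapeConfig, default_landscape_config, gen_landscape

logger = logging.getLogger("vegres.pipeline")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PreprocessParams:
    despike_window: int = 7
    despike_k: float = 4.0
    period: int = 24
    trend_smoother: int = 47
    lowpass: int = 25
    seasonal_smoother: int = 121
    robust: bool = True
    max_gap: int = 4
    max_missing_frac: float = 0.2


@dataclass
class DetectionParams:
    slope_window: int = 18
    percentile: float = 99.0
    pre_win: int = 24
    post_win: int = 24
    alpha: float = 0.05
    fit_years: float = 5.0
    r2_min: float = 0.5
    min_search: int = 12


@dataclass
class PipelineConfig:
    """Fully serializable configuration for one pipeline run."""

    seed: int = 0
    landscape: LandscapeConfig = field(default_factory=default_landscape_config)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    relate: RelateConfig = field(default_factory=RelateConfig)
    predictors: tuple = ("aridity", "si", "interannual_norm")
    metrics: tuple = ("lambda_ac1", "lambda_var")
    landcover_whitelist: tuple | None = None  # None = all natural classes present

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "landscape" in d and not isinstance(d["landscape"], LandscapeConfig):
            d["landscape"] = LandscapeConfig.from_dict(d["landscape"])
        for key, typ in (
            ("preprocess", PreprocessParams),
            ("detection", DetectionParams),
            ("relate", RelateConfig),
        ):
            if key in d and not isinstance(d[key], typ):
                d[key] = typ(**{k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()})
        for key in ("predictors", "metrics", "landcover_whitelist"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def load_config(path) -> PipelineConfig:
    """Load a pipeline configuration from a YAML file."""
    with open(path) as fh:
        return PipelineConfig.from_dict(yaml.safe_load(fh) or {})


def _save_config(config: PipelineConfig, out_dir: Path) -> None:
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, default_flow_style=None, sort_keys=False)


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are retained on disk."""


def stage_simulate(config: PipelineConfig, out_dir: Path) -> None:
    landscape = gen_landscape(config.landscape, seed=config.seed)
    landscape.to_dir(out_dir / "landscape")
    logger.info("simulate: %d pixels, %d steps", len(landscape.pixels), landscape.veg.shape[1] if landscape.veg.size else 0)


def stage_preprocess(config: PipelineConfig, out_dir: Path) -> None:
    land = out_dir / "landscape"
    series_list = io.read_veg_cube(land / "veg.nc")
    labels = io.read_labels(land / "labels.csv")
    natural = set(labels.iloc[:, 0].unique()) if config.landcover_whitelist is None else set(
        config.landcover_whitelist
    )
    known = set(labels.to_numpy().astype(str).ravel()) | natural
    eligible = landcover_mask(labels, natural_classes=natural, known_classes=known)
    eligible.to_frame().to_csv(out_dir / "eligibility.csv")
    logger.info("preprocess: %d/%d pixels eligible", int(eligible.sum()), len(eligible))

    pp = config.preprocess
    residuals = []
    dropped = 0
    for s in series_list:
        if not bool(eligible.get(s.pixel_id, False)):
            continue
        try:
            clean = despike(s, window=pp.despike_window, k=pp.despike_k)
            res = stl_residual(
                clean,
                period=pp.period,
                trend_smoother=pp.trend_smoother,
                lowpass=pp.lowpass,
                seasonal_smoother=pp.seasonal_smoother,
                robust=pp.robust,
                max_gap=pp.max_gap,
                max_missing_frac=pp.max_missing_frac,
            )
        except ValueError:
            dropped += 1
            continue
        residuals.append(res)
    logger.info("preprocess: %d residual series (%d dropped)", len(residuals), dropped)
    if not residuals:
        warnings.warn("no eligible pixels after masking; downstream stages will be empty")
        # write an empty marker so downstream stages exit cleanly
        pd.DataFrame(columns=["pixel_id"]).to_csv(out_dir / "resilience.csv", index=False)
        return
    io.write_residual_cube(out_dir / "residuals.nc", residuals, seed=config.seed)


def stage_resilience(config: PipelineConfig, out_dir: Path) -> None:
    path = out_dir / "residuals.nc"
    if not path.exists():
        logger.info("resilience: no residuals, skipping")
        return
    rows = []
    for r in io.read_residual_cube(path):
        est = estimate_resilience(r)
        rows.append(
            {
                "pixel_id": r.pixel_id,
                "ac1": est.ac1,
                "variance": est.variance,
                "noise_var": est.noise_var,
                "lambda_ac1": est.lambda_ac1,
                "lambda_var": est.lambda_var,
                "n_eff": est.n_eff,
                "flags": ";".join(est.flags),
            }
        )
    pd.DataFrame(rows).to_csv(out_dir / "resilience.csv", index=False)
    logger.info("resilience: %d pixels estimated", len(rows))


def stage_perturbations(config: PipelineConfig, out_dir: Path) -> None:
    path = out_dir / "residuals.nc"
    if not path.exists():
        logger.info("perturbations: no residuals, skipping")
        return
    det = config.detection
    rows = []
    totals = {"candidates": 0, "validated": 0, "accepted": 0}
    for r in io.read_residual_cube(path):
        fits, counts = find_recovery_events(
            r,
            slope_window=det.slope_window,
            percentile=det.percentile,
            pre_win=det.pre_win,
            post_win=det.post_win,
            alpha=det.alpha,
            fit_years=det.fit_years,
            r2_min=det.r2_min,
            min_search=det.min_search,
        )
        for k in totals:
            totals[k] += counts[k]
        for f in fits:
            p = f.perturbation
            rows.append(
                {
                    "pixel_id": r.pixel_id,
                    "peak_sample": p.peak_sample if p else -1,
                    "peak_time": r.time0 + (p.peak_sample * r.dt if p else np.nan),
                    "slope_at_peak": p.slope_at_peak if p else np.nan,
                    "ks_p": p.ks_p if p else np.nan,
                    "min_index": p.min_index if p else -1,
                    "x0": f.x0,
                    "r": f.r,
                    "r2": f.r2,
                    "accepted": f.accepted,
                    "reason": f.reason,
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "pixel_id", "peak_sample", "peak_time", "slope_at_peak", "ks_p",
            "min_index", "x0", "r", "r2", "accepted", "reason",
        ],
    ).to_csv(out_dir / "events.csv", index=False)
    logger.info(
        "perturbations: %(candidates)d candidates, %(validated)d KS-validated, %(accepted)d fits accepted",
        totals,
    )


def stage_climate(config: PipelineConfig, out_dir: Path) -> None:
    land = out_dir / "landscape"
    precip_list = io.read_precip_cube(land / "precip.nc")
    pixels = pd.read_csv(land / "pixels.csv")
    pet = dict(zip(pixels["pixel_id"], pixels["pet_mm"])) if len(pixels) else {}
    rows = []
    for pr in precip_list:
        cm = climate_metrics(pr, pet_mm=pet.get(pr.pixel_id, np.nan))
        rows.append(
            {
                "pixel_id": pr.pixel_id,
                "map_mm": cm.map_mm,
                "pet_mm": cm.pet_mm,
                "aridity": cm.aridity,
                "si": cm.si,
                "interannual_norm": cm.interannual_norm,
            }
        )
    pd.DataFrame(
        rows, columns=["pixel_id", "map_mm", "pet_mm", "aridity", "si", "interannual_norm"]
    ).to_csv(out_dir / "climate.csv", index=False)
    logger.info("climate: %d pixels", len(rows))


def stage_relate(config: PipelineConfig, out_dir: Path) -> None:
    res_path = out_dir / "resilience.csv"
    cli_path = out_dir / "climate.csv"
    resil = pd.read_csv(res_path) if res_path.exists() else pd.DataFrame(columns=["pixel_id"])
    if resil.empty:
        results_to_frame([]).to_csv(out_dir / "relationships.csv", index=False)
        logger.warning("relate: no resilience estimates; wrote empty relationships table")
        return
    clim = pd.read_csv(cli_path)
    pixels = pd.read_csv(out_dir / "landscape" / "pixels.csv")
    merged = resil.merge(clim, on="pixel_id").merge(
        pixels[["pixel_id", "landcover"]], on="pixel_id"
    )
    merged.to_csv(out_dir / "merged.csv", index=False)

    rel_cfg = dataclasses.replace(config.relate, seed=config.seed)
    all_results = []
    for metric in config.metrics:
        for predictor in config.predictors:
            all_results.extend(
                relate(merged, predictor, metric, landcover_col="landcover", config=rel_cfg)
            )
    frame = results_to_frame(all_results)
    frame.to_csv(out_dir / "relationships.csv", index=False)
    n_rep = int(frame["reportable"].sum()) if len(frame) else 0
    logger.info("relate: %d relationships (%d reportable)", len(frame), n_rep)


STAGES = (
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("resilience", stage_resilience),
    ("perturbations", stage_perturbations),
    ("climate", stage_climate),
    ("relate", stage_relate),
)


def run_pipeline(config: PipelineConfig, out_dir, stages=None) -> Path:
    """Run the configured stages, returning the run directory.

    ``stages`` restricts execution to a subset (by name) for re-running
    individual steps from existing intermediates. Any stage failure
    aborts with a stage-tagged error; prior outputs remain on disk.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "pipeline.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        _save_config(config, out_dir)
        for name, fn in STAGES:
            if stages is not None and name not in stages:
                continue
            try:
                fn(config, out_dir)
            except Exception as exc:  # noqa: BLE001 - re-tagged with stage name
                raise StageError(f"stage '{name}' failed: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return out_dir
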