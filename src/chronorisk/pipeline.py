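"""Stage orchestration: each analysis stage as a function over an output directory.

The stages mirror the analysis protocol end to end:

``simulate`` -> ``encode`` -> ``gam``          (chronicle model, 1700-2000)
``simulate`` -> ``screen`` -> ``risk`` -> ``classify`` / ``pca``   (1970-2000)

Every stage reads its inputs from, and writes its outputs and a
:class:`~chronorisk.config.RunManifest` into, one working directory, so
stages can be run separately or chained with :func:`run_all`.  All
randomness derives from the configured seed via fixed per-stage offsets.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as cls
from . import encoder, gam, io, maxent, screening
from . import pca_attribution as pca
from .config import PipelineConfig, RunManifest
from .grids import PeriodSpec
from .simulate import SimulationParams, simulate_all

logger = logging.getLogger("chronorisk")

GAM_COVARIATES = ["popd", "popc", "cropland", "grazing", "temperature", "regional_temperature"]
SDM_CANDIDATES = ["popc", "popd", "cropland", "grazing", "uopp", "bio3", "bio7", "bio8", "bio14"]

_STAGE_STREAMS = {"simulate": 11, "screen": 13, "risk": 17, "classify": 19, "pca": 23}


def _rng(cfg: PipelineConfig, stage: str) -> np.random.Generator:
    return np.random.default_rng([cfg.rng_seed % (2**31), _STAGE_STREAMS[stage]])


def _require(path: Path, stage: str, produced_by: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {path.name}; run the '{produced_by}' stage first"
        )
    return path


def _write_json(obj: dict, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, allow_nan=False,
                               default=float) + "\n")


def _manifest(cfg: PipelineConfig, stage: str, out: Path, inputs: list[Path], outputs: list[Path]) -> None:
    man = RunManifest(stage, cfg.rng_seed, cfg.to_dict())
    for p in inputs:
        man.add_input(p)
    man.outputs = [str(p) for p in outputs]
    man.write(out / f"manifest_{stage}.json")


def sim_params_from_config(cfg: PipelineConfig) -> SimulationParams:
    return SimulationParams(
        n_cells_x=cfg.sim_n_cells_x,
        n_cells_y=cfg.sim_n_cells_y,
        origin_lon=cfg.sim_origin_lon,
        origin_lat=cfg.sim_origin_lat,
        cell_degrees=cfg.grid_cell_degrees,
        study_start=cfg.study_start,
        period_years=cfg.period_years,
        n_periods=cfg.n_periods,
        slice_years=cfg.slice_years,
        detection_prob=cfg.sim_detection_prob,
        n_extant=cfg.sim_n_extant,
        seed=cfg.rng_seed,
    )


def _periods(cfg: PipelineConfig) -> PeriodSpec:
    return PeriodSpec(cfg.study_start, cfg.period_years, cfg.n_periods)


def _load_stack(out: Path, cfg: PipelineConfig) -> io.CovariateStack:
    raster_dir = _require(out / "rasters", "any", "simulate")
    files = sorted(raster_dir.glob("*_*.asc"))
    paths: dict[str, dict[int, Path]] = {}
    for f in files:
        name, year = f.stem.rsplit("_", 1)
        paths.setdefault(name, {})[int(year)] = f
    years = sorted({y for d in paths.values() for y in d})
    return io.read_raster_stack({n: [d[y] for y in years] for n, d in paths.items()}, years)


def _window_env(stack: io.CovariateStack, start: int, end: int) -> io.CovariateStack:
    """Static stack: per-layer mean of the slices within [start, end)."""
    idx = np.flatnonzero((stack.years >= start) & (stack.years < end))
    if len(idx) == 0:
        raise encoder.CoverageError(f"no covariate slices within [{start},{end})")
    layers = {n: arr[idx].mean(axis=0)[None] for n, arr in stack.layers.items()}
    return io.CovariateStack(stack.grid, np.asarray([start]), layers, stack.valid.copy())


def run_simulate(cfg: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    params = sim_params_from_config(cfg)
    stack, records, truth, extant, poly = simulate_all(params)
    occ_path, ext_path = out / "occurrences.csv", out / "extant.csv"
    io.write_occurrences([io.OccurrenceRecord(*r) for r in records.itertuples(index=False)], occ_path)
    io.write_occurrences([io.OccurrenceRecord(*r) for r in extant.itertuples(index=False)], ext_path)
    io.write_range_polygon(poly, out / "range.geojson")
    truth.to_frame().to_csv(out / "truth.csv", index=False, lineterminator="\n")
    io.write_raster_stack(stack, out / "rasters")
    report = {
        "n_historical": int(len(records)),
        "n_extant": int(len(extant)),
        "n_cells": int(params.grid.n_cells),
        "n_extinct_cells": int((truth.first_extinct >= 0).sum()),
    }
    _write_json(report, out / "simulate_report.json")
    _manifest(cfg, "simulate", out, [], [occ_path, ext_path])
    logger.info("simulate: %(n_historical)d historical, %(n_extant)d extant records", report)
    return report


def run_encode(cfg: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    records = io.occurrences_to_frame(io.read_occurrences(_require(out / "occurrences.csv", "encode", "simulate")))
    stack = _load_stack(out, cfg)
    periods = _periods(cfg)
    fates = encoder.encode_fates(records, stack.grid, periods, cfg.presence_rows)
    fates, n_dropped = encoder.attach_covariates(fates, stack, periods, GAM_COVARIATES)
    fates.to_csv(out / "fates.csv", index=False, lineterminator="\n")
    report = {
        "n_rows": int(len(fates)),
        "n_presence_rows": int((fates["fate"] == 0).sum()),
        "n_extinction_events": int((fates["fate"] == 1).sum()),
        "n_dropped_nodata": n_dropped,
    }
    _write_json(report, out / "encode_report.json")
    _manifest(cfg, "encode", out, [out / "occurrences.csv"], [out / "fates.csv"])
    logger.info("encode: %(n_rows)d fate rows, %(n_extinction_events)d extinction events", report)
    return report


def run_gam(cfg: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    fates = pd.read_csv(_require(out / "fates.csv", "gam", "encode"))
    candidates = [c for c in GAM_COVARIATES if c in fates.columns]
    kept, screen_log = gam.screen_collinear_predictors(
        fates, candidates, r_threshold=cfg.collinear_threshold
    )
    spec = gam.GamSpec.default(kept)
    fit = gam.fit_gam(fates, spec)
    report = {"screening": screen_log, "kept_variables": kept, **fit.summary()}
    _write_json(report, out / "gam_summary.json")
    outputs = [out / "gam_summary.json"]
    for v in kept:
        grid_vals = np.linspace(fates[v].min(), fates[v].max(), 50)
        curve = gam.partial_effect(fit, v, grid_vals)
        p = out / f"partial_{v}.csv"
        curve.to_csv(p, index=False, lineterminator="\n")
        outputs.append(p)
    _manifest(cfg, "gam", out, [out / "fates.csv"], outputs)
    logger.info("gam: n=%d, deviance explained %.3f", fit.n, fit.deviance_explained)
    return report


def run_screen(cfg: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    records = io.occurrences_to_frame(io.read_occurrences(_require(out / "occurrences.csv", "screen", "simulate")))
    extant = io.occurrences_to_frame(io.read_occurrences(_require(out / "extant.csv", "screen", "simulate")))
    poly = io.read_range_polygon(_require(out / "range.geojson", "screen", "simulate"))
    screened, counts = screening.screen_extinctions(
        records, extant, poly, cfg.buffer_km, (cfg.screen_start, cfg.screen_end)
    )
    ext = screened[screened["is_extinction"]]
    rarefied = screening.rarefy(ext, cfg.rarefy_km, cfg.rarefy_cell_arcmin)
    screened["kept_after_rarefaction"] = screened["id"].isin(rarefied["id"])
    screened.to_csv(out / "screened.csv", index=False, lineterminator="\n")
    report = {**counts, "n_rarefied": int(len(rarefied))}
    if len(rarefied) >= 2:
        lon, lat = rarefied["lon"], rarefied["lat"]
        bbox = (float(lon.min()), float(lat.min()), float(lon.max()) + 1e-9, float(lat.max()) + 1e-9)
        radii = np.linspace(0, cfg.buffer_km * 4, 9)[1:]
        kf = screening.ripley_k(rarefied, radii, bbox, n_sims=99, rng=_rng(cfg, "screen"))
        report["ripley_k"] = kf.to_frame().round(6).to_dict(orient="list")
    _write_json(report, out / "screening_report.json")
    _manifest(cfg, "screen", out, [out / "occurrences.csv", out / "extant.csv"], [out / "screened.csv"])
    logger.info(
        "screen: %(n_screened)d in window -> %(outside_range)d outside range, "
        "%(outside_buffers)d outside buffers, %(total_extinction)d extinction, "
        "%(n_rarefied)d after rarefaction", report,
    )
    return report


def run_risk(cfg: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    screened = pd.read_csv(_require(out / "screened.csv", "risk", "screen"))
    presences = screened[screened["is_extinction"] & screened["kept_after_rarefaction"]]
    if len(presences) < 5:
        raise ValueError(f"only {len(presences)} extinction presences; cannot fit the risk model")
    stack = _window_env(_load_stack(out, cfg), cfg.screen_start, cfg.screen_end)
    rng = _rng(cfg, "risk")
    candidates = [v for v in SDM_CANDIDATES if v in stack.layers]
    bg_cells, bg_env = maxent.sample_background(stack, cfg.background_n, rng, candidates)
    ix, iy = stack.grid.assign_xy(presences["lon"].to_numpy(float), presences["lat"].to_numpy(float))
    pres_cells = stack.grid.cell_id(ix, iy)
    pres_env = stack.env_matrix(pres_cells, candidates)

    retained, _ = maxent.prescreen_variables(
        pres_env, bg_env, cfg.prescreen_runs, cfg.reg_multiplier, rng=rng
    )
    fs = maxent.FeatureSet.from_background(bg_env[retained])
    pilot = maxent.fit_maxent(fs.transform(pres_env[retained]), fs.transform(bg_env[retained]), fs,
                              cfg.reg_multiplier)
    retained, corr_log = maxent.correlation_filter(
        bg_env[retained], pilot.percent_contribution(), cfg.correlation_threshold
    )
    rep = maxent.replicate_fit(
        pres_env, bg_env, stack, retained, cfg.replicates, cfg.test_fraction,
        cfg.reg_multiplier, rng,
    )
    io.write_ascii_grid(rep.surface, stack.grid, out / "risk_surface.asc")
    surf_flat = rep.surface.ravel()
    model_report = {
        "retained_variables": retained,
        "correlation_drops": corr_log,
        "mean_test_auc": rep.mean_auc,
        "sd_test_auc": rep.sd_auc,
        "percent_contribution": rep.mean_contributions,
        "permutation_importance": rep.mean_importance,
        "background_cells": [int(c) for c in bg_cells],
        "presence_cells": [int(c) for c in pres_cells],
        "risk_range": [float(np.nanmin(surf_flat)), float(np.nanmax(surf_flat))],
    }
    _write_json(model_report, out / "sdm_model.json")
    _manifest(cfg, "risk", out, [out / "screened.csv"], [out / "risk_surface.asc", out / "sdm_model.json"])
    logger.info("risk: %d presences, %d background cells, mean test AUC %.3f",
                len(presences), len(bg_cells), rep.mean_auc)
    return model_report


def run_classify(cfg: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    surface, grid, _ = io.read_ascii_grid(_require(out / "risk_surface.asc", "classify", "risk"))
    model = json.loads(_require(out / "sdm_model.json", "classify", "risk").read_text())
    extant = io.occurrences_to_frame(io.read_occurrences(_require(out / "extant.csv", "classify", "simulate")))

    def at_cells(cell_ids):
        c = np.asarray(cell_ids)
        return surface[c // grid.n_x, c % grid.n_x]

    pres_scores = at_cells(model["presence_cells"])
    bg_scores = at_cells(model["background_cells"])
    ok = np.isfinite(pres_scores), np.isfinite(bg_scores)
    thr = cls.max_sss_threshold(pres_scores[ok[0]], bg_scores[ok[1]])
    result = cls.classify_sites(surface, grid, extant, thr.threshold, cfg.jenks_k,
                                region_col="region" if "region" in extant.columns else None)
    result.sites.to_csv(out / "classification.csv", index=False, lineterminator="\n")
    report = {
        "threshold": thr.threshold,
        "sensitivity": thr.sensitivity,
        "specificity": thr.specificity,
        **result.to_report(),
    }
    _write_json(report, out / "classification_report.json")
    _manifest(cfg, "classify", out, [out / "risk_surface.asc", out / "extant.csv"],
              [out / "classification.csv", out / "classification_report.json"])
    logger.info("classify: threshold %.3f, notable %.2f%%", thr.threshold, result.notable_percentage)
    return report


def run_pca(cfg: PipelineConfig, out: str | Path) -> dict:
    out = Path(out)
    screened = pd.read_csv(_require(out / "screened.csv", "pca", "screen"))
    model = json.loads(_require(out / "sdm_model.json", "pca", "risk").read_text())
    stack = _window_env(_load_stack(out, cfg), cfg.screen_start, cfg.screen_end)
    ext = screened[screened["is_extinction"]]
    variables = model["retained_variables"]
    mat, dropped = pca.extract_env_at_records(ext, stack, variables)
    result = pca.pca(mat, standardize=True)
    cum2 = pca.variance_summary(result, min(2, len(variables)))
    result.loadings_frame().to_csv(out / "pca_loadings.csv", lineterminator="\n")
    result.contributions_frame().to_csv(out / "pca_contributions.csv", lineterminator="\n")
    report = {
        "variables": variables,
        "n_records": int(len(mat)),
        "n_dropped_nodata": dropped,
        "explained_ratio": [float(r) for r in result.explained_ratio],
        "first_two_components_pct": cum2,
        "contributions_pc1": {v: float(c) for v, c in zip(variables, result.contributions[:, 0])},
        "contributions_pc2": {v: float(c) for v, c in
                              zip(variables, result.contributions[:, min(1, result.contributions.shape[1] - 1)])},
    }
    _write_json(report, out / "pca_report.json")
    _manifest(cfg, "pca", out, [out / "screened.csv"], [out / "pca_report.json"])
    logger.info("pca: first two components %.2f%%", cum2)
    return report


STAGES = {
    "simulate": run_simulate,
    "encode": run_encode,
    "gam": run_gam,
    "screen": run_screen,
    "risk": run_risk,
    "classify": run_classify,
    "pca": run_pca,
}


def run_all(cfg: PipelineConfig, out: str | Path) -> dict:
    """Chain every stage; returns (and writes) the combined report."""
    out = Path(out)
    report = {name: stage(cfg, out) for name, stage in STAGES.items()}
    _write_json(report, out / "report.json")
    return report
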