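"""End-to-end orchestration: simulate -> prepare -> env -> models -> report.

Each stage is a pure function on dataframes; :func:`run_pipeline` chains
them, writes CSV artifacts plus a JSON manifest per stage (inputs, seed,
row counts at every filter), and is deterministic given the master seed.
Per-stage seeds are derived from the master seed by stable hashing of the
stage name.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import hier, trend
from .config import ScenarioConfig
from .diagnostics import observer_vs_brood_kde, residual_semivariogram
from .environment import (ClimateWindow, select_window, snow_cover_at,
                          snowmelt_metrics)
from .records import (EventKind, StageDurations, apply_monitoring_precedence,
                      compute_event_interval, dedup_broods,
                      elevation_with_uncertainty, mean_observer_day_table)
from .reporting import phenology_summary
from .synth import SyntheticDataset, simulate

logger = logging.getLogger(__name__)

__all__ = ["stage_seed", "prepare_broods", "environment_stage",
            "PipelineResult", "run_pipeline"]


def stage_seed(master: int, stage: str) -> int:
    """Stable per-stage seed below 2**31."""
    return int((master * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31))


# ---------------------------------------------------------------------------
# prepare: records -> deduplicated broods with intervals and covariates

def prepare_broods(records: pd.DataFrame, effort: pd.DataFrame,
                   cells: pd.DataFrame, subgrids: dict,
                   stages: StageDurations | None = None,
                   seed: int = 0) -> tuple[pd.DataFrame, dict]:
    """Monitoring precedence, hatching intervals, dedup, covariates.

    Returns the brood table (one row per retained brood, with hatching
    interval, elevation mean/SD by precision class, region and mean
    observer day) and a manifest of record counts at each filter.
    """
    required = {"record_id", "cell_id", "year", "day", "atlas_code",
                "observer_id", "precision_class", "source"}
    missing = required - set(records.columns)
    if missing:
        raise KeyError(f"records missing columns: {sorted(missing)}")
    stages = stages or StageDurations.default()
    counts = {"input": len(records)}
    recs = apply_monitoring_precedence(records)
    counts["after_precedence"] = len(recs)

    iv = [compute_event_interval(int(d), c, stages)
          for d, c in zip(recs["day"], recs["atlas_code"])]
    recs = recs.assign(hatch_lo=[v.earliest for v in iv],
                       hatch_hi=[v.latest for v in iv])

    rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
    kept_rows = []
    for (cell, year), g in recs.groupby(["cell_id", "year"], sort=True):
        g = g.sort_values("record_id").reset_index(drop=True)
        res = dedup_broods(list(zip(g["hatch_lo"], g["hatch_hi"])), rng,
                           observers=list(g["observer_id"]),
                           obs_days=list(g["day"]))
        kept_rows.append(g.iloc[res.selected_indices])
    broods = pd.concat(kept_rows, ignore_index=True)
    counts["after_dedup"] = len(broods)

    broods["hatch_mean"] = 0.5 * (broods["hatch_lo"] + broods["hatch_hi"])
    broods["hatch_width"] = broods["hatch_hi"] - broods["hatch_lo"]

    elev_mean = np.empty(len(broods))
    elev_sd = np.empty(len(broods))
    for i, row in enumerate(broods.itertuples()):
        sub = (int(row.subcell_row), int(row.subcell_col)) \
            if "subcell_row" in broods.columns else None
        point = (float(row.nest_elevation_m)
                 if "nest_elevation_m" in broods.columns else None)
        elev_mean[i], elev_sd[i] = elevation_with_uncertainty(
            row.precision_class, subgrids[row.cell_id], sub, point)
    broods["elevation_mean"] = elev_mean
    broods["elevation_sd"] = elev_sd

    broods = broods.merge(cells[["cell_id", "region", "x_km", "y_km"]],
                          on="cell_id", how="left")
    obs_day = mean_observer_day_table(effort)
    broods = broods.merge(obs_day, on=["cell_id", "year"], how="left")
    n_no_effort = int(broods["observer_day"].isna().sum())
    if n_no_effort:
        logger.warning("%d broods lack in-window observer effort",
                       n_no_effort)
    counts["missing_observer_day"] = n_no_effort
    return broods, counts


# ---------------------------------------------------------------------------
# env: snowmelt metrics, window selection, covariates

def environment_stage(dataset: SyntheticDataset, broods: pd.DataFrame,
                      use_true_windows: bool = False) -> dict:
    """Derive environmental covariates for a prepared brood table."""
    metrics_rows = []
    series_by = {}
    for s in dataset.snow:
        m = snowmelt_metrics(s)
        series_by[(s.cell_id, s.year)] = s
        if m is not None:
            metrics_rows.append((s.cell_id, s.year, m.meltstart, m.meltend))
    snow_metrics = pd.DataFrame(metrics_rows, columns=[
        "cell_id", "year", "meltstart", "meltend"])

    cc = dataset.config.climate
    cid_index = {c: i for i, c in enumerate(dataset.climate.cell_ids)}
    yr_index = {y: i for i, y in enumerate(dataset.climate.years)}
    ci = broods["cell_id"].map(cid_index).to_numpy()
    yi = broods["year"].map(yr_index).to_numpy()
    hatch = broods["hatch_mean"].to_numpy(dtype=float)

    windows: dict[str, ClimateWindow] = {}
    scans = {}
    for var, arr, true_win in (
            ("temperature", dataset.climate.temperature, cc.temp_window),
            ("precipitation", dataset.climate.precipitation,
             cc.precip_window)):
        if use_true_windows:
            windows[var] = ClimateWindow(true_win[0], true_win[1], var,
                                         float("nan"))
            continue
        daily = arr[ci, yi, :]
        scan = select_window(daily, hatch, variable=var)
        scans[var] = scan
        if scan.window is None:
            logger.warning("window scan found no qualifying window for %s; "
                           "using the generator's configured window", var)
            windows[var] = ClimateWindow(true_win[0], true_win[1], var,
                                         float("nan"))
        else:
            windows[var] = scan.window

    climate_long = dataset.climate.to_long_df()
    windex = dataset.winter_index
    from .environment import attach_covariates
    enriched = attach_covariates(broods, climate_long,
                                 windows["temperature"],
                                 windows["precipitation"],
                                 snow_metrics, windex)
    enriched = enriched.merge(snow_metrics[["cell_id", "year", "meltend"]],
                              on=["cell_id", "year"], how="left")
    return {"broods": enriched, "snow_metrics": snow_metrics,
            "windows": windows, "scans": scans, "series_by": series_by,
            "winter_index": windex}


def build_event_table(broods: pd.DataFrame, series_by: dict,
                      stages: StageDurations | None = None) -> pd.DataFrame:
    """Per-brood event intervals (hatching, laying, nest building) with
    melt metrics and snow cover at the mean event date."""
    stages = stages or StageDurations.default()
    rows = []
    for row in broods.itertuples():
        if not np.isfinite(row.meltstart) or not np.isfinite(row.meltend):
            continue
        series = series_by.get((row.cell_id, row.year))
        for kind in (EventKind.HATCHING, EventKind.LAYING,
                     EventKind.NEST_BUILDING):
            ev = compute_event_interval(int(row.day), row.atlas_code,
                                        stages, kind)
            day = int(round(ev.mean))
            try:
                cover = snow_cover_at(series, day) if series else np.nan
            except ValueError:
                cover = np.nan
            rows.append((row.year, row.elevation_mean, kind.value, ev.mean,
                         ev.earliest, ev.latest, row.meltstart, row.meltend,
                         cover))
    return pd.DataFrame(rows, columns=[
        "year", "elevation", "kind", "day_mean", "day_earliest",
        "day_latest", "meltstart", "meltend", "snow_cover"])


# ---------------------------------------------------------------------------
# full pipeline

@dataclass
class PipelineResult:
    dataset: SyntheticDataset
    broods: pd.DataFrame
    env: dict
    trend_fits: dict
    hier_posteriors: dict
    convergence: dict
    summary: object
    kde_containment: float
    semivariogram: object
    manifests: dict


def run_pipeline(config: ScenarioConfig | None = None, seed: int = 0,
                 out_dir: str | Path | None = None,
                 chains: int = 4, n_iter: int = 2000,
                 models: tuple[str, ...] = ("spatiotemporal",
                                            "environmental"),
                 use_true_windows: bool = False) -> PipelineResult:
    """Run every stage on one synthetic scenario.

    With ``out_dir`` set, each stage writes its CSV artifacts and a JSON
    manifest.  The master ``seed`` overrides ``config.seed`` and feeds
    every stage through stable per-stage seeds.
    """
    config = config or ScenarioConfig()
    config.seed = stage_seed(seed, "simulate")
    manifests: dict[str, dict] = {}
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    dataset = simulate(config)
    manifests["simulate"] = {
        "seed": config.seed, "n_cells": config.n_cells,
        "n_true_broods": len(dataset.truth.broods),
        "n_records": len(dataset.records),
        "n_effort_rows": len(dataset.effort),
    }

    broods, counts = prepare_broods(
        dataset.records, dataset.effort, dataset.landscape.cells,
        dataset.landscape.subgrids, seed=stage_seed(seed, "prepare"))
    broods = broods.dropna(subset=["observer_day"]).reset_index(drop=True)
    manifests["prepare"] = {"seed": stage_seed(seed, "prepare"), **counts,
                            "n_broods": len(broods)}

    env = environment_stage(dataset, broods,
                            use_true_windows=use_true_windows)
    eb = env["broods"]
    manifests["env"] = {
        "windows": {v: [w.start, w.end] for v, w in env["windows"].items()},
        "n_excluded_env": int(eb["excluded_env"].sum()),
    }

    trend_fits = {}
    tr_seed = stage_seed(seed, "trend")
    fit_h = trend.fit_trend(eb, "hatch_mean", elevation_col="elevation_mean")
    trend_fits["hatch_mean"] = trend.simulate_posterior(fit_h, 2000,
                                                        seed=tr_seed)
    sm = env["snow_metrics"].merge(
        dataset.landscape.cells[["cell_id", "elev_mean"]], on="cell_id")
    for resp in ("meltstart", "meltend"):
        f = trend.fit_trend(sm, resp, elevation_col="elev_mean")
        trend_fits[resp] = trend.simulate_posterior(f, 2000, seed=tr_seed + 1)
    manifests["trend"] = {"seed": tr_seed,
                          "responses": sorted(trend_fits)}

    hier_posteriors = {}
    convergence = {}
    hseed = stage_seed(seed, "hier")
    for model in models:
        sub = eb if model == "spatiotemporal" else eb[~eb["excluded_env"]]
        data = hier.build_model_data(sub, model)
        post = hier.fit_hier(data, chains=chains, n_iter=n_iter, seed=hseed)
        hier_posteriors[model] = post
        convergence[model] = hier.convergence_report(post)
    manifests["hier"] = {
        "seed": hseed, "chains": chains, "n_iter": n_iter,
        "converged": {m: bool(convergence[m].attrs["passed"])
                      for m in convergence},
    }

    events = build_event_table(eb, env["series_by"])
    summary = phenology_summary(events)

    obs_pts = dataset.effort.merge(
        dataset.landscape.cells[["cell_id", "elev_mean"]], on="cell_id")
    obs_xy = np.repeat(
        obs_pts[["day", "elev_mean"]].to_numpy(dtype=float),
        obs_pts["n_persons"].to_numpy(), axis=0)
    brd_xy = eb[["hatch_mean", "elevation_mean"]].to_numpy(dtype=float)
    _, _, containment = observer_vs_brood_kde(obs_xy, brd_xy)

    ref_model = models[-1]
    post = hier_posteriors[ref_model]
    resid = (post.data.h_obs
             - post.flat("h").mean(axis=0))
    sub = eb if ref_model == "spatiotemporal" else eb[~eb["excluded_env"]]
    sub = sub.dropna(subset=hier_required_columns(ref_model))
    semiv = residual_semivariogram(resid,
                                   sub[["x_km", "y_km"]].to_numpy())
    manifests["diagnose"] = {"kde_containment": containment}

    if out is not None:
        dataset.records.to_csv(out / "records.csv", index=False)
        dataset.effort.to_csv(out / "effort.csv", index=False)
        dataset.truth.broods.to_csv(out / "truth.csv", index=False)
        broods.to_csv(out / "broods_prepared.csv", index=False)
        eb.to_csv(out / "broods_enriched.csv", index=False)
        env["snow_metrics"].to_csv(out / "snow_metrics.csv", index=False)
        summary.annual.to_csv(out / "phenology_annual.csv", index=False)
        summary.event_means.to_csv(out / "phenology_events.csv", index=False)
        for m, p in hier_posteriors.items():
            hier.coefficient_table(p).to_csv(
                out / f"coefficients_{m}.csv", index=False)
            convergence[m].to_csv(out / f"convergence_{m}.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifests, fh, indent=2, default=str)

    return PipelineResult(dataset, broods, env, trend_fits, hier_posteriors,
                          convergence, summary, containment, semiv,
                          manifests)


def hier_required_columns(model: str) -> list[str]:
    cols = ["hatch_mean", "hatch_width", "region", "year", "elevation_mean",
            "elevation_sd", "observer_day"]
    if model == "environmental":
        cols += ["winter_intensity", "temperature_mean", "temperature_sd",
                 "precipitation_mean", "precipitation_sd", "meltstart"]
    return cols
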