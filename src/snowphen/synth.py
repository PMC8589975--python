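"""Synthetic alpine study system: landscape, snow, climate, broods, observers.

Everything downstream of raw data is testable against this generator because
it stores its own ground truth: true hatching dates and covariates per
brood, true melt days per snow series, and the standardization scales used
to turn configured standardized effects into days.

The generative model for a brood's true hatching date is

    hatch = alpha[region] + sum_k beta_k * z_k + gamma[year] + eps,

with z_k the empirically standardized covariates (elevation, elevation^2,
year, elevation x year, winter intensity, spring precipitation, meltstart,
spring temperature), gamma[year] ~ N(0, sigma_year) and
eps ~ N(0, sigma_resid).  The observation process then scatters
stage-specific behavioural records around each hatch date according to
observer effort and per-stage detectability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendars import doy_to_iso
from .config import ScenarioConfig
from .environment import SnowSeries

__all__ = [
    "Landscape", "ClimateFields", "BroodTruth", "SyntheticDataset",
    "generate_landscape", "generate_snow_series", "generate_climate",
    "generate_winter_series", "generate_broods", "generate_observations",
    "simulate", "make_window_scenario",
]

_SUBGRID = 5  # 200-m sub-cells per 1-km cell side

# generation stage windows: day - hatch in [lo, hi) -> atlas code; these are
# half-open refinements of the closed offset bounds in the default
# stage-duration table, so every back-computed interval contains the truth
_GEN_STAGES: tuple[tuple[str, float, float], ...] = (
    ("nest_building", -22.0, -14.0),
    ("incubation", -14.0, 0.0),
    ("food_for_young", 0.0, 20.0),
    ("fledglings", 20.0, 34.0),
)

_PREDICTORS = ("elevation", "elevation2", "year", "elevation_year",
               "winter", "precipitation", "meltstart", "temperature")


def _rng(config: ScenarioConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.seed, stage]))


# ---------------------------------------------------------------------------
# landscape

@dataclass
class Landscape:
    cells: pd.DataFrame                 # cell_id, x_km, y_km, region, elev...
    subgrids: dict[int, np.ndarray]     # cell_id -> 5x5 200-m elevations

    def subgrid(self, cell_id: int) -> np.ndarray:
        return self.subgrids[cell_id]


def generate_landscape(config: ScenarioConfig) -> Landscape:
    """Scatter 1-km cells over the domain with 200-m elevation sub-grids.

    Cell coordinates are uniform over a square domain; region labels follow
    the domain quadrant (W/E x N/S), echoing contiguous biogeographic
    regions.  Each cell's 25 sub-cell elevations are normal around a cell
    level drawn uniformly from the configured elevation range; the reported
    1-km mean and SD are exactly the sample statistics of the sub-cells.
    """
    config.validate()
    rng = _rng(config, 1)
    n = config.n_cells
    lo, hi = config.elevation_range_m
    x = rng.uniform(0, config.domain_km, n)
    y = rng.uniform(0, config.domain_km, n)
    half = config.domain_km / 2
    quadrant = np.where(x < half,
                        np.where(y >= half, "NA", "WA"),
                        np.where(y >= half, "EA", "SA"))
    centers = rng.uniform(lo + 2 * config.subgrid_relief_sd_m,
                          hi - 2 * config.subgrid_relief_sd_m, n)
    subgrids: dict[int, np.ndarray] = {}
    means = np.empty(n)
    sds = np.empty(n)
    for i in range(n):
        g = centers[i] + rng.normal(0, config.subgrid_relief_sd_m,
                                    (_SUBGRID, _SUBGRID))
        subgrids[i] = g
        means[i] = g.mean()
        sds[i] = g.std(ddof=1)
    cells = pd.DataFrame({
        "cell_id": np.arange(n), "x_km": x, "y_km": y,
        "region": quadrant, "elev_mean": means, "elev_sd": sds,
    })
    return Landscape(cells, subgrids)


# ---------------------------------------------------------------------------
# snow

def generate_snow_series(landscape: Landscape, config: ScenarioConfig,
                         ) -> list[SnowSeries]:
    """Daily snow-cover fraction per cell-year with stored true melt days.

    Each series sits at the winter maximum through ``meltstart - 1``,
    decreases strictly over the melt period and stays at the summer minimum
    from ``meltend`` on.  Melt onset shifts later with elevation; melt
    duration is normal (default mean 70 d, SD 16 d).  The idealised curves
    are noise-free so that the metric operations can be checked for exact
    ground-truth recovery.
    """
    years = config.year_list
    if not years:
        raise ValueError("empty year range")
    rng = _rng(config, 2)
    m = config.melt
    days = np.arange(1, 366)
    out: list[SnowSeries] = []
    elev = landscape.cells["elev_mean"].to_numpy()
    mid_year = float(np.mean(years))
    year_anom = {y: rng.normal(0.0, m.year_anomaly_sd_days) for y in years}
    for ci, cell_id in enumerate(landscape.cells["cell_id"]):
        de = elev[ci] - 2450.0
        trend = (m.year_trend_per_decade_at_2450
                 + m.year_trend_slope_per_m_decade * de)
        for year in years:
            onset_mean = (m.onset_at_2450_m + m.onset_slope_per_m * de
                          + trend * (year - mid_year) / 10.0
                          + year_anom[year])
            ms = int(np.clip(round(rng.normal(onset_mean, m.onset_sd_days)),
                             15, 170))
            dur = max(0, int(round(rng.normal(m.duration_mean_days,
                                              m.duration_sd_days))))
            me = ms + dur
            cover = np.full(365, m.winter_max_fraction)
            drop = m.winter_max_fraction - m.summer_min_fraction
            if dur > 0:
                melt_days = np.arange(ms, me)
                cover[melt_days - 1] = (m.winter_max_fraction
                                        - drop * (melt_days - ms + 1)
                                        / (dur + 1))
            cover[me - 1:] = m.summer_min_fraction
            out.append(SnowSeries(cell_id, year, days, cover,
                                  true_meltstart=ms, true_meltend=me))
    return out


def snow_truth_table(series: list[SnowSeries]) -> pd.DataFrame:
    return pd.DataFrame({
        "cell_id": [s.cell_id for s in series],
        "year": [s.year for s in series],
        "true_meltstart": [s.true_meltstart for s in series],
        "true_meltend": [s.true_meltend for s in series],
    })


# ---------------------------------------------------------------------------
# climate

@dataclass
class ClimateFields:
    cell_ids: np.ndarray
    years: list[int]
    days: np.ndarray                  # 1..n_days
    temperature: np.ndarray           # (n_cells, n_years, n_days)
    precipitation: np.ndarray
    temp_subgrid_sd: np.ndarray       # (n_cells,) constant per cell
    precip_subgrid_sd: np.ndarray

    def window_mean(self, variable: str, window: tuple[int, int]) -> np.ndarray:
        """(n_cells, n_years) mean over the inclusive day window."""
        arr = getattr(self, "temperature" if variable == "temperature"
                      else "precipitation")
        lo, hi = window
        sel = (self.days >= lo) & (self.days <= hi)
        return arr[:, :, sel].mean(axis=2)

    def to_long_df(self) -> pd.DataFrame:
        """Long format (cell_id, year, day, variable, value, subgrid_sd)."""
        nc, ny, nd = self.temperature.shape
        cell = np.repeat(self.cell_ids, ny * nd)
        year = np.tile(np.repeat(self.years, nd), nc)
        day = np.tile(self.days, nc * ny)
        frames = []
        for var, arr, sd in (("temperature", self.temperature,
                              self.temp_subgrid_sd),
                             ("precipitation", self.precipitation,
                              self.precip_subgrid_sd)):
            frames.append(pd.DataFrame({
                "cell_id": cell, "year": year, "day": day,
                "variable": var, "value": arr.reshape(-1),
                "subgrid_sd": np.repeat(sd, ny * nd),
            }))
        return pd.concat(frames, ignore_index=True)


def generate_climate(landscape: Landscape, config: ScenarioConfig,
                     ) -> ClimateFields:
    """Daily temperature / precipitation per cell-year.

    Seasonal cycle + elevation lapse (temperature only) + cell-year
    anomalies at monthly resolution + daily noise.  Monthly anomalies give
    sliding-window aggregates realistic temporal signal structure.
    Sub-grid SDs scale with each cell's relief.
    """
    rng = _rng(config, 3)
    cc = config.climate
    years = config.year_list
    nc, ny, nd = config.n_cells, len(years), cc.n_days
    days = np.arange(1, nd + 1)
    month_of_day = np.minimum((days - 1) // 30, 11)
    elev = landscape.cells["elev_mean"].to_numpy()

    seasonal_t = -2.0 + 12.0 * np.sin(np.pi * (days - 20) / 365.0)
    base_t = (seasonal_t[None, :]
              + cc.temp_lapse_per_m * (elev - 2450.0)[:, None])
    anom_t = rng.normal(0, cc.temp_monthly_anom_sd, (nc, ny, 12))
    temp = (base_t[:, None, :] + anom_t[:, :, month_of_day]
            + rng.normal(0, cc.temp_daily_sd, (nc, ny, nd)))

    seasonal_p = cc.precip_mean_mm_day * (1 + 0.3 * np.sin(2 * np.pi * days
                                                           / 365.0))
    anom_p = rng.normal(0, cc.precip_monthly_anom_sd, (nc, ny, 12))
    precip = (seasonal_p[None, None, :] + anom_p[:, :, month_of_day]
              + rng.normal(0, cc.precip_daily_sd, (nc, ny, nd)))
    np.clip(precip, 0.0, None, out=precip)

    relief = landscape.cells["elev_sd"].to_numpy()
    relief_factor = relief / max(float(relief.mean()), 1e-9)
    return ClimateFields(
        landscape.cells["cell_id"].to_numpy(), years, days, temp, precip,
        cc.temp_subgrid_sd * relief_factor,
        cc.precip_subgrid_sd * relief_factor,
    )


def generate_winter_series(config: ScenarioConfig) -> pd.DataFrame:
    """Winter station series (year, mean_temp, mean_snow_depth)."""
    rng = _rng(config, 4)
    w = config.winter
    years = np.array(config.year_list)
    z = rng.multivariate_normal(
        [0.0, 0.0],
        [[1.0, w.temp_depth_corr], [w.temp_depth_corr, 1.0]], len(years))
    return pd.DataFrame({
        "year": years,
        "mean_temp": w.temp_mean_c + w.temp_sd_c * z[:, 0],
        "mean_snow_depth": np.maximum(
            w.depth_mean_cm + w.depth_sd_cm * z[:, 1], 5.0),
    })


# ---------------------------------------------------------------------------
# broods

@dataclass
class BroodTruth:
    """True broods plus the standardization used to generate them."""

    broods: pd.DataFrame
    scales: dict[str, tuple[float, float]]   # predictor -> (center, sd)
    coefficients: dict[str, float] = field(default_factory=dict)
    region_intercepts: dict[str, float] = field(default_factory=dict)
    year_effects: pd.DataFrame | None = None


def generate_broods(landscape: Landscape, climate: ClimateFields,
                    snow: list[SnowSeries], winter_index,
                    config: ScenarioConfig) -> BroodTruth:
    """Draw true broods from the configured linear predictor.

    Cells are sampled with weight peaking at 2450 m (the species' density
    optimum), so the brood elevation distribution is narrower than the
    landscape's.  True covariates are drawn consistently with the
    measurement model used downstream: elevation from the cell's sub-grid
    distribution, temperature/precipitation as cell window means plus
    sub-grid noise, meltstart and winter intensity as cell-year / year
    scalars.  All z-scores use the empirical mean/SD over the brood set, so
    configured standardized coefficients are exactly the data-generating
    effects per empirical SD.
    """
    for k in _PREDICTORS:
        if k not in config.true_coefficients:
            raise ValueError(f"true_coefficients missing entry {k!r}")
    rng = _rng(config, 5)
    cells = landscape.cells
    years = np.array(config.year_list)
    n = config.n_broods

    w = np.exp(-0.5 * ((cells["elev_mean"].to_numpy() - 2450.0) / 250.0) ** 2)
    cell_idx = rng.choice(len(cells), size=n, p=w / w.sum())
    year_idx = rng.integers(0, len(years), size=n)
    year = years[year_idx]
    elev_true = rng.normal(cells["elev_mean"].to_numpy()[cell_idx],
                           cells["elev_sd"].to_numpy()[cell_idx])

    cc = config.climate
    tmean = climate.window_mean("temperature", cc.temp_window)
    pmean = climate.window_mean("precipitation", cc.precip_window)
    temp_true = (tmean[cell_idx, year_idx]
                 + rng.normal(0, climate.temp_subgrid_sd[cell_idx]))
    precip_true = (pmean[cell_idx, year_idx]
                   + rng.normal(0, climate.precip_subgrid_sd[cell_idx]))

    melt_by = {(s.cell_id, s.year): s.true_meltstart for s in snow}
    melt = np.array([melt_by[(cells["cell_id"].iloc[c], y)]
                     for c, y in zip(cell_idx, year)], dtype=float)
    wint = np.array([winter_index.score_for(y) for y in year])

    raw = {
        "elevation": elev_true, "year": year.astype(float),
        "winter": wint, "precipitation": precip_true,
        "meltstart": melt, "temperature": temp_true,
    }
    # standardization constants come from the *observable* side of each
    # covariate (cell means, window means), matching the convention of the
    # downstream analysis, which scales by the raw SD of observed values;
    # the z-scores themselves use the latent true values
    observed = {
        "elevation": cells["elev_mean"].to_numpy()[cell_idx],
        "year": year.astype(float), "winter": wint,
        "precipitation": pmean[cell_idx, year_idx],
        "meltstart": melt, "temperature": tmean[cell_idx, year_idx],
    }
    scales = {k: (float(v.mean()), float(np.std(v, ddof=1)))
              for k, v in observed.items()}
    z = {k: (v - scales[k][0]) / scales[k][1] for k, v in raw.items()}
    z["elevation2"] = z["elevation"] ** 2
    z["elevation_year"] = z["elevation"] * z["year"]

    beta = config.true_coefficients
    region = cells["region"].to_numpy()[cell_idx]
    lin = np.array([config.region_intercepts[r] for r in region])
    for k in _PREDICTORS:
        lin += beta[k] * z[k]
    gamma = rng.normal(0, config.sigma_year_days, len(years))
    resid = rng.normal(0, config.sigma_resid_days, n)
    hatch = lin + gamma[year_idx] + resid

    if config.second_brood_proportion > 0:
        second = rng.random(n) < config.second_brood_proportion
        hatch = hatch + np.where(second, config.second_brood_offset_days, 0.0)
    else:
        second = np.zeros(n, dtype=bool)

    # reported 200-m sub-cell: drawn with weights matching the downstream
    # measurement model (true elevation ~ Normal(sub-cell value, 3x3
    # neighbourhood SD)), so location uncertainty is neither under- nor
    # overstated for 200-m-precision records
    sub_r = np.empty(n, dtype=int)
    sub_c = np.empty(n, dtype=int)
    nb_sd_cache: dict = {}
    for i in range(n):
        cid = cells["cell_id"].iloc[cell_idx[i]]
        g = landscape.subgrids[cid]
        if cid not in nb_sd_cache:
            sds = np.empty_like(g)
            for r_ in range(g.shape[0]):
                for c_ in range(g.shape[1]):
                    nb = g[max(r_ - 1, 0):r_ + 2, max(c_ - 1, 0):c_ + 2]
                    sds[r_, c_] = max(nb.std(ddof=1), 1e-6)
            nb_sd_cache[cid] = sds
        sds = nb_sd_cache[cid]
        logw = -0.5 * ((elev_true[i] - g) / sds) ** 2 - np.log(sds)
        w_sub = np.exp(logw - logw.max()).ravel()
        flat = int(rng.choice(g.size, p=w_sub / w_sub.sum()))
        sub_r[i], sub_c[i] = divmod(flat, g.shape[1])

    broods = pd.DataFrame({
        "brood_id": np.arange(n),
        "cell_id": cells["cell_id"].to_numpy()[cell_idx],
        "year": year, "region": region,
        "true_hatch": hatch, "true_elevation": elev_true,
        "true_temperature": temp_true, "true_precipitation": precip_true,
        "true_meltstart": melt, "true_winter": wint,
        "year_effect": gamma[year_idx], "second_brood": second,
        "subcell_row": sub_r, "subcell_col": sub_c,
    })
    for k in ("elevation", "year", "winter", "precipitation", "meltstart",
              "temperature"):
        broods[f"z_{k}"] = z[k]
    year_eff = pd.DataFrame({"year": years, "gamma": gamma})
    return BroodTruth(broods, scales, dict(beta),
                      dict(config.region_intercepts), year_eff)


# ---------------------------------------------------------------------------
# observations

def generate_observations(truth: BroodTruth, landscape: Landscape,
                          config: ScenarioConfig,
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Citizen-science records and the observer-effort log.

    Observer effort is a log-Gaussian intensity over (date, elevation),
    wider than the brood distribution on both axes; the number of persons
    per cell-day is Poisson.  A brood in stage *s* on a visit day is
    detected by each person with probability ``detectability[s]``; each
    detection becomes one record whose atlas code is the active stage.
    Cell-years of designated monitoring cells contribute exact hatch-day
    records that take precedence downstream.
    """
    if not config.detectability:
        raise ValueError("empty detectability map")
    rng = _rng(config, 6)
    eff = config.effort
    cells = landscape.cells
    years = config.year_list
    d0, d1 = eff.season
    days = np.arange(d0, d1 + 1)
    date_f = np.exp(-0.5 * ((days - eff.date_peak) / eff.date_sd) ** 2)
    elev_f = np.exp(-0.5 * ((cells["elev_mean"].to_numpy() - eff.elev_peak_m)
                            / eff.elev_sd_m) ** 2)
    lam = eff.peak_rate * elev_f[:, None] * date_f[None, :]

    effort_rows = []
    persons: dict[tuple, np.ndarray] = {}
    for ci, cell_id in enumerate(cells["cell_id"]):
        for year in years:
            counts = rng.poisson(lam[ci])
            nz = np.flatnonzero(counts)
            for j in nz:
                ids = rng.integers(0, 2000, size=counts[j])
                persons[(cell_id, year, int(days[j]))] = ids
                effort_rows.append((cell_id, year, int(days[j]),
                                    int(counts[j])))
    effort = pd.DataFrame(effort_rows,
                          columns=["cell_id", "year", "day", "n_persons"])

    mon_cells = set()
    n_mon = int(round(config.monitoring_cell_fraction * len(cells)))
    if n_mon:
        mon_cells = set(rng.choice(cells["cell_id"].to_numpy(), n_mon,
                                   replace=False).tolist())

    classes = list(config.precision_mix)
    class_p = np.array([config.precision_mix[c] for c in classes])
    rec_rows = []
    rid = 0
    b = truth.broods
    for i in range(len(b)):
        cell_id = b["cell_id"].iloc[i]
        year = int(b["year"].iloc[i])
        h = float(b["true_hatch"].iloc[i])
        e_true = float(b["true_elevation"].iloc[i])
        if cell_id in mon_cells:
            day = int(np.clip(round(h), 1, 365))
            rec_rows.append((rid, b["brood_id"].iloc[i], cell_id, year, day,
                             "hatch", "monitor", "nest", "monitoring",
                             b["subcell_row"].iloc[i],
                             b["subcell_col"].iloc[i],
                             e_true + rng.normal(0.0, 0.5)))
            rid += 1
            # citizen records still accrue here; monitoring precedence
            # downstream is what removes them
        for code, lo, hi in _GEN_STAGES:
            p = config.detectability.get(code, 0.0)
            if p <= 0:
                continue
            for day in range(int(np.ceil(h + lo)), int(np.ceil(h + hi))):
                ids = persons.get((cell_id, year, day))
                if ids is None:
                    continue
                hits = ids[rng.random(len(ids)) < p]
                for obs in hits:
                    cls = classes[rng.choice(len(classes), p=class_p)]
                    nest_elev = (e_true + rng.normal(0.0, 0.5)
                                 if cls == "nest" else np.nan)
                    rec_rows.append((rid, b["brood_id"].iloc[i], cell_id,
                                     year, day, code, int(obs), cls,
                                     "citizen", b["subcell_row"].iloc[i],
                                     b["subcell_col"].iloc[i], nest_elev))
                    rid += 1
    cap = config.max_records_per_observer_day
    if cap is not None and rec_rows:
        kept = [r for r in rec_rows if r[8] == "monitoring"]
        by_visit: dict[tuple, list] = {}
        for row in rec_rows:
            if row[8] == "citizen":
                by_visit.setdefault((row[2], row[3], row[4], row[6]),
                                    []).append(row)
        for rows in by_visit.values():
            if len(rows) <= cap:
                kept.extend(rows)
            else:
                take = rng.choice(len(rows), size=cap, replace=False)
                kept.extend(rows[t] for t in sorted(take))
        kept.sort(key=lambda r: r[0])
        rec_rows = kept
    records = pd.DataFrame(rec_rows, columns=[
        "record_id", "brood_id", "cell_id", "year", "day", "atlas_code",
        "observer_id", "precision_class", "source", "subcell_row",
        "subcell_col", "nest_elevation_m"])
    records["date_iso"] = [doy_to_iso(y, d) for y, d in
                           zip(records["year"], records["day"])]
    return records, effort


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class SyntheticDataset:
    config: ScenarioConfig
    landscape: Landscape
    snow: list[SnowSeries]
    climate: ClimateFields
    winter_stations: pd.DataFrame
    winter_index: object
    truth: BroodTruth
    records: pd.DataFrame
    effort: pd.DataFrame

    @property
    def snow_truth(self) -> pd.DataFrame:
        return snow_truth_table(self.snow)


def simulate(config: ScenarioConfig | None = None) -> SyntheticDataset:
    """Generate a complete synthetic dataset under one configuration."""
    from .environment import winter_intensity

    config = config or ScenarioConfig()
    landscape = generate_landscape(config)
    snow = generate_snow_series(landscape, config)
    climate = generate_climate(landscape, config)
    stations = generate_winter_series(config)
    windex = winter_intensity(stations["year"], stations["mean_temp"],
                              stations["mean_snow_depth"])
    truth = generate_broods(landscape, climate, snow, windex, config)
    records, effort = generate_observations(truth, landscape, config)
    return SyntheticDataset(config, landscape, snow, climate, stations,
                            windex, truth, records, effort)


def make_window_scenario(n_broods: int, signal_window: tuple[int, int],
                         slope: float = 8.0, noise_sd: float = 2.0,
                         n_days: int = 140, seed: int = 0,
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Planted-signal fixture for window-selection recovery.

    Daily climate is white noise per brood; hatch dates are an affine
    function of the mean over ``signal_window`` (inclusive days) plus
    noise.  Returns ``(daily, hatch_days)`` ready for
    :func:`snowphen.environment.select_window`.
    """
    rng = np.random.default_rng(seed)
    daily = rng.normal(3.0, 1.5, (n_broods, n_days))
    lo, hi = signal_window
    signal = daily[:, lo - 1:hi].mean(axis=1)
    hatch = 170.0 + slope * (signal - signal.mean())
    hatch = hatch + rng.normal(0, noise_sd, n_broods)
    return daily, hatch
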