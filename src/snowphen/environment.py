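"""Snowmelt metrics, climate-window selection and covariate attachment.

Snowmelt timing per 1x1 km cell and season is read off the daily snow-cover
fraction: *meltstart* is the first day after maximal snow cover (last tied
maximum day + 1, i.e. the first day from which cover can only decrease) and
*meltend* the first day attaining the post-meltstart minimum.  Spring
climate predictors are chosen by a sliding-window scan that correlates
window-aggregated temperature / precipitation with brood hatching dates.
Winter severity is summarised as the first principal component of mean
winter temperature and mean winter snow depth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calendars import MAY_15

logger = logging.getLogger(__name__)

#: default candidate window lengths (days) for the sliding-window scan
DEFAULT_WINDOW_LENGTHS: tuple[int, ...] = (1, 7, 14, 30, 45, 61, 90)

#: latest admissible window end (May 15, the lower 2.5% quantile of
#: hatching dates in the system this emulates)
WINDOW_LAST_END: int = MAY_15


@dataclass(frozen=True)
class SnowSeries:
    """Daily snow-cover fraction for one cell and season."""

    cell_id: object
    year: int
    days: np.ndarray       # strictly increasing day axis
    cover: np.ndarray      # fractions in [0, 1]
    true_meltstart: int | None = None   # generator ground truth, if synthetic
    true_meltend: int | None = None

    def __post_init__(self) -> None:
        if len(self.days) != len(self.cover):
            raise ValueError("days and cover differ in length")


@dataclass(frozen=True)
class SnowmeltMetrics:
    meltstart: float
    meltend: float

    def __post_init__(self) -> None:
        if self.meltend < self.meltstart:
            raise ValueError("meltend before meltstart")

    @property
    def duration(self) -> float:
        return self.meltend - self.meltstart


def meltstart(series: SnowSeries) -> float:
    """First day after maximal snow cover (NaN when undefined).

    Ties at the maximum resolve to the *last* tied day, so the returned day
    is the first from which cover can only decrease.  A constant series, or
    a maximum attained on the final day, has no defined melt onset.
    """
    cover = np.asarray(series.cover, dtype=float)
    if cover.size == 0 or np.all(cover == cover[0]):
        logger.warning("constant snow series for cell %s year %s: "
                       "meltstart undefined", series.cell_id, series.year)
        return float("nan")
    last_max = int(np.flatnonzero(cover == cover.max())[-1])
    if last_max == len(cover) - 1:
        logger.warning("snow maximum on final day for cell %s year %s",
                       series.cell_id, series.year)
        return float("nan")
    return float(series.days[last_max] + 1)


def meltend(series: SnowSeries, melt_start: float) -> float:
    """First day at the post-meltstart minimum of the series."""
    if not np.isfinite(melt_start):
        return float("nan")
    days = np.asarray(series.days)
    cover = np.asarray(series.cover, dtype=float)
    after = days >= melt_start
    sub = cover[after]
    first_min = int(np.flatnonzero(sub == sub.min())[0])
    return float(days[after][first_min])


def snowmelt_metrics(series: SnowSeries) -> SnowmeltMetrics | None:
    ms = meltstart(series)
    if not np.isfinite(ms):
        return None
    return SnowmeltMetrics(ms, meltend(series, ms))


def snow_cover_at(series: SnowSeries, day: int) -> float:
    idx = np.searchsorted(series.days, day)
    if idx >= len(series.days) or series.days[idx] != day:
        raise ValueError(f"day {day} outside snow series range")
    return float(series.cover[idx])


def classify_event(day: float, metrics: SnowmeltMetrics) -> str:
    """'before_melt' / 'during_melt' / 'after_melt'; melt is closed on both
    ends, so an event on meltstart or meltend day counts as during melt."""
    if day < metrics.meltstart:
        return "before_melt"
    if day <= metrics.meltend:
        return "during_melt"
    return "after_melt"


# ---------------------------------------------------------------------------
# sliding-window climate predictor selection

@dataclass(frozen=True)
class ClimateWindow:
    start: int
    end: int
    variable: str
    correlation: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class WindowScanResult:
    window: ClimateWindow | None
    diagnostics: pd.DataFrame   # one row per (length, end) with correlation
    qualifying_lengths: list[int] = field(default_factory=list)


def select_window(daily: np.ndarray, hatch_days: np.ndarray,
                  variable: str = "precipitation",
                  lengths: tuple[int, ...] = DEFAULT_WINDOW_LENGTHS,
                  last_end: int = WINDOW_LAST_END,
                  top_k: int = 20) -> WindowScanResult:
    """Select the climate window most correlated with hatching dates.

    ``daily[i, d]`` is the climate value for brood *i* on day ``d + 1``; the
    scan slides, for each candidate length L, a window over end-days L..
    ``last_end``, aggregates by the window mean, and computes the Pearson
    correlation with ``hatch_days`` across broods.  A length qualifies when
    its ``top_k`` highest |correlation| end-days are consecutive; among
    qualifying lengths the window with maximal |correlation| wins.  Returns
    a result with ``window=None`` (plus full diagnostics) when no length
    qualifies.
    """
    daily = np.asarray(daily, dtype=float)
    hatch = np.asarray(hatch_days, dtype=float)
    if daily.ndim != 2 or daily.shape[0] != hatch.shape[0]:
        raise ValueError("daily climate must be (n_broods, n_days)")
    if daily.shape[0] < 3:
        raise ValueError("need at least 3 broods for a correlation scan")
    n_days = min(daily.shape[1], last_end)
    csum = np.concatenate(
        [np.zeros((daily.shape[0], 1)), np.cumsum(daily[:, :n_days], axis=1)],
        axis=1)
    hz = hatch - hatch.mean()
    hss = float(hz @ hz)
    rows = []
    best_per_length: dict[int, tuple[int, float]] = {}
    qualifying: list[int] = []
    for L in lengths:
        ends = np.arange(L, n_days + 1)
        if len(ends) < top_k:
            logger.warning("window length %d has only %d end-days; "
                           "disqualified", L, len(ends))
            continue
        means = (csum[:, ends] - csum[:, ends - L]) / L
        mz = means - means.mean(axis=0)
        denom = np.sqrt(np.einsum("ij,ij->j", mz, mz) * hss)
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (hz @ mz) / denom, np.nan)
        for e, c in zip(ends, corr):
            rows.append((L, int(e - L + 1), int(e), float(c)))
        a = np.abs(np.nan_to_num(corr, nan=-np.inf))
        top = np.sort(ends[np.argsort(a)[-top_k:]])
        consecutive = bool(np.all(np.diff(top) == 1))
        ibest = int(np.argmax(a))
        best_per_length[L] = (int(ends[ibest]), float(corr[ibest]))
        if consecutive:
            qualifying.append(L)
    diag = pd.DataFrame(rows, columns=["length", "start", "end", "correlation"])
    if not qualifying:
        logger.info("no window length met the consecutive-top-%d criterion",
                    top_k)
        return WindowScanResult(None, diag, [])
    Lbest = max(qualifying, key=lambda L: abs(best_per_length[L][1]))
    end, corr = best_per_length[Lbest]
    win = ClimateWindow(end - Lbest + 1, end, variable, corr)
    return WindowScanResult(win, diag, qualifying)


# ---------------------------------------------------------------------------
# winter-intensity index

@dataclass(frozen=True)
class WinterIndex:
    years: np.ndarray
    scores: np.ndarray        # PC1 score per year, mean 0
    loadings: np.ndarray      # (temp, depth) loading vector, unit norm
    variance_explained: float

    def score_for(self, year: int) -> float:
        idx = np.flatnonzero(self.years == year)
        if len(idx) == 0:
            raise KeyError(f"no winter index for year {year}")
        return float(self.scores[idx[0]])


def winter_intensity(years, winter_temps, snow_depths) -> WinterIndex:
    """PC1 of standardized winter temperature and snow depth.

    The sign is fixed so that colder and snowier winters score higher
    (negative temperature loading, positive depth loading).
    """
    years = np.asarray(years)
    t = np.asarray(winter_temps, dtype=float)
    d = np.asarray(snow_depths, dtype=float)
    if len(t) != len(d) or len(t) != len(years):
        raise ValueError("winter series lengths differ")
    if len(t) < 3:
        raise ValueError("need at least 3 years for the winter index")
    if np.std(t, ddof=1) == 0 or np.std(d, ddof=1) == 0:
        raise ValueError("zero-variance winter series")
    zt = (t - t.mean()) / np.std(t, ddof=1)
    zd = (d - d.mean()) / np.std(d, ddof=1)
    X = np.column_stack([zt, zd])
    cov = np.cov(X, rowvar=False, ddof=1)
    evals, evecs = np.linalg.eigh(cov)
    v = evecs[:, -1]
    # harsher winter = colder + snowier
    if v[1] - v[0] < 0:
        v = -v
    elif v[1] - v[0] == 0 and (X @ v @ zd) < 0:
        v = -v
    scores = X @ v
    return WinterIndex(years, scores - scores.mean(), v,
                       float(evals[-1] / evals.sum()))


# ---------------------------------------------------------------------------
# covariate attachment

def attach_covariates(broods: pd.DataFrame,
                      climate_means: pd.DataFrame,
                      temp_window: ClimateWindow,
                      precip_window: ClimateWindow,
                      snow_metrics: pd.DataFrame,
                      winter_index: WinterIndex) -> pd.DataFrame:
    """Join per-brood environmental covariates with sub-grid uncertainty.

    ``climate_means`` is a long table (cell_id, year, day, variable, value,
    subgrid_sd); per brood the chosen window's mean value and the mean of
    the daily sub-grid SDs are attached for temperature and precipitation,
    along with the cell-year meltstart and the year's winter-intensity
    score (a yearly scalar, so its measurement SD is 0).  Broods whose
    cell-year lacks climate coverage are flagged ``excluded_env=True``.
    """
    out = broods.copy()
    for var, win in (("temperature", temp_window),
                     ("precipitation", precip_window)):
        sub = climate_means[(climate_means["variable"] == var)
                            & (climate_means["day"] >= win.start)
                            & (climate_means["day"] <= win.end)]
        g = sub.groupby(["cell_id", "year"])
        n_days = g["value"].count()
        agg = pd.DataFrame({
            f"{var}_mean": g["value"].mean(),
            f"{var}_sd": g["subgrid_sd"].mean(),
            f"{var}_ndays": n_days,
        }).reset_index()
        complete = agg[f"{var}_ndays"] == win.length
        agg.loc[~complete, [f"{var}_mean", f"{var}_sd"]] = np.nan
        out = out.merge(agg.drop(columns=f"{var}_ndays"),
                        on=["cell_id", "year"], how="left")
    out = out.merge(snow_metrics[["cell_id", "year", "meltstart"]],
                    on=["cell_id", "year"], how="left")
    wi = pd.DataFrame({"year": winter_index.years,
                       "winter_intensity": winter_index.scores})
    out = out.merge(wi, on="year", how="left")
    out["winter_intensity_sd"] = 0.0
    env_cols = ["temperature_mean", "precipitation_mean", "meltstart",
                "winter_intensity"]
    out["excluded_env"] = out[env_cols].isna().any(axis=1)
    n_exc = int(out["excluded_env"].sum())
    if n_exc:
        logger.info("%d broods lack complete environmental covariates "
                    "and are excluded from the environmental model", n_exc)
    return out
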