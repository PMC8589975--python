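"""Headline phenology summaries and derived coefficient quantities.

Summarises how breeding events sit relative to the snowmelt window (mean
snow-cover fraction at each event, fractions of broods before / during /
after melt per year, annual mean hatching dates, elevation-band profiles)
and converts the precipitation effect into an interpretable delay
equivalent: the additional window-total precipitation associated with a
one-day shift in hatching date.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .environment import SnowmeltMetrics, classify_event

logger = logging.getLogger(__name__)

__all__ = ["PhenologySummary", "phenology_summary",
           "precipitation_delay_equivalent"]


@dataclass
class PhenologySummary:
    event_means: pd.DataFrame      # per event kind: mean snow cover etc.
    annual: pd.DataFrame           # per year: fractions + mean hatch date
    elevation_bands: pd.DataFrame  # Fig-1-style per-band means

    @property
    def during_melt_hatching_fraction(self) -> float:
        w = self.annual["n_broods"]
        return float(np.average(self.annual["frac_during"], weights=w))


def phenology_summary(events: pd.DataFrame,
                      snow_lookup=None,
                      band_width_m: float = 200.0) -> PhenologySummary:
    """Summarise breeding events against the snowmelt window.

    ``events`` has one row per (brood, event kind) with columns ``year``,
    ``elevation``, ``kind``, ``day_mean``, ``day_earliest``, ``day_latest``,
    ``meltstart``, ``meltend`` and (optionally, or via ``snow_lookup``)
    ``snow_cover``.  ``snow_lookup(row) -> fraction`` resolves the
    snow-cover fraction at the mean event date when no column is present.
    Events are classified against the closed melt window at their mean
    date; error margins use the earliest/latest dates.
    """
    if events.empty:
        raise ValueError("no events to summarise")
    df = events.copy()
    if "snow_cover" not in df.columns:
        if snow_lookup is None:
            raise ValueError("need a snow_cover column or a snow_lookup")
        df["snow_cover"] = [snow_lookup(row) for _, row in df.iterrows()]
    df["melt_class"] = [
        classify_event(d, SnowmeltMetrics(ms, me))
        for d, ms, me in zip(df["day_mean"], df["meltstart"], df["meltend"])
    ]

    ev_rows = []
    for kind, g in df.groupby("kind"):
        ev_rows.append((kind, len(g), float(g["snow_cover"].mean()),
                        float(g["day_mean"].mean()),
                        float(g["day_earliest"].mean()),
                        float(g["day_latest"].mean())))
    event_means = pd.DataFrame(ev_rows, columns=[
        "kind", "n", "mean_snow_cover", "mean_day", "mean_earliest",
        "mean_latest"])

    hatch = df[df["kind"] == "hatching"]
    if hatch.empty:
        raise ValueError("no hatching events present")
    ann_rows = []
    for year, g in hatch.groupby("year"):
        frac = g["melt_class"].value_counts(normalize=True)
        ann_rows.append((int(year), len(g),
                         float(frac.get("before_melt", 0.0)),
                         float(frac.get("during_melt", 0.0)),
                         float(frac.get("after_melt", 0.0)),
                         float(g["day_mean"].mean()),
                         float(g["day_mean"].std(ddof=1))
                         if len(g) > 1 else 0.0))
    annual = pd.DataFrame(ann_rows, columns=[
        "year", "n_broods", "frac_before", "frac_during", "frac_after",
        "mean_hatch_day", "sd_hatch_day"])

    lo = np.floor(df["elevation"].min() / band_width_m) * band_width_m
    band = (np.floor((df["elevation"] - lo) / band_width_m) * band_width_m
            + lo)
    df["band"] = band
    band_rows = []
    for (kind, b), g in df.groupby(["kind", "band"]):
        band_rows.append((kind, float(b), float(b + band_width_m), len(g),
                          float(g["snow_cover"].mean()),
                          float(g["day_mean"].mean())))
    bands = pd.DataFrame(band_rows, columns=[
        "kind", "band_low_m", "band_high_m", "n", "mean_snow_cover",
        "mean_day"])
    return PhenologySummary(event_means, annual, bands)


def precipitation_delay_equivalent(beta_std: float, raw_sd_mm_per_day: float,
                                   window_days: int) -> float:
    """Window-total precipitation (mm) per one-day hatching delay.

    The standardized effect ``beta_std`` (days per SD of mm/day) converts
    to days per mm/day via the raw SD; dividing the window length by that
    per-(mm/day) slope gives the total additional millimetres over the
    window that shift hatching by one day.  Returns inf (logged as not
    estimable) when the effect is zero.
    """
    if raw_sd_mm_per_day <= 0:
        raise ValueError("raw SD must be positive")
    if window_days <= 0:
        raise ValueError("window length must be positive")
    if beta_std == 0:
        logger.warning("zero precipitation effect: delay equivalent "
                       "not estimable")
        return float("inf")
    per_mm_day = beta_std / raw_sd_mm_per_day
    return window_days / per_mm_day
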