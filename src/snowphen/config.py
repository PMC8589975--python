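"""Scenario configuration for the synthetic study system.

The defaults describe a desk-scale emulation of a 20-year alpine
citizen-science dataset: ~120 one-kilometre grid cells between 1500 and
3100 m asl in four biogeographic regions, ~700 true broods whose hatching
dates follow a linear predictor on standardized spatiotemporal and
environmental covariates, and an observation process with stage-dependent
detectability, heterogeneous observer effort over date x elevation, and
three location-precision classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

#: standardized true effects (days per SD of the predictor); the observer-day
#: effect is zero in the generator because observer timing is an artefact of
#: the observation process, not a cause of hatching dates.
DEFAULT_COEFFICIENTS: dict[str, float] = {
    "elevation": -0.6,
    "elevation2": 0.92,
    "observer_day": 0.0,
    "year": -0.68,
    "elevation_year": -0.12,
    "winter": -0.05,
    "precipitation": 1.14,
    "meltstart": 0.6,
    "temperature": -1.05,
}

#: region intercepts in day-of-year units (EA/NA/SA around Jun 24-26,
#: WA around Jun 20).
DEFAULT_REGION_INTERCEPTS: dict[str, float] = {
    "EA": 175.0,
    "NA": 176.0,
    "SA": 177.0,
    "WA": 171.0,
}

DEFAULT_DETECTABILITY: dict[str, float] = {
    "nest_building": 0.12,
    "incubation": 0.08,
    "food_for_young": 0.30,
    "fledglings": 0.15,
}

DEFAULT_PRECISION_MIX: dict[str, float] = {
    "nest": 0.05,
    "200m": 0.35,
    "1km": 0.60,
}


@dataclass
class EffortConfig:
    """Log-Gaussian observer-effort intensity over (date, elevation).

    The surface is deliberately wider than the brood distribution along both
    axes, so effort covers the breeding season on either side of its peak.
    """

    peak_rate: float = 0.40        # expected persons/cell/day at the peak
    date_peak: float = 170.0       # day-of-year of maximum effort
    date_sd: float = 55.0          # spread along the date axis (days)
    elev_peak_m: float = 2300.0
    elev_sd_m: float = 700.0
    season: tuple[int, int] = (60, 273)  # days with any effort at all


@dataclass
class MeltConfig:
    """Snowmelt timing of the synthetic snow series.

    Melt onset shifts later with elevation, carries strong shared
    year-to-year anomalies (so the meltstart predictor is not collinear
    with elevation; across-brood correlation stays below ~0.6), and has a
    long-term trend that advances at low elevations while delaying at high
    ones.
    """

    onset_at_2450_m: float = 118.0   # mean meltstart day at 2450 m asl
    onset_slope_per_m: float = 0.03  # days later per metre of elevation
    onset_sd_days: float = 8.0       # cell-year residual spread
    year_anomaly_sd_days: float = 13.0   # shared anomaly per winter
    year_trend_per_decade_at_2450: float = -2.0
    year_trend_slope_per_m_decade: float = 0.005
    duration_mean_days: float = 70.0
    duration_sd_days: float = 16.0
    winter_max_fraction: float = 1.0
    summer_min_fraction: float = 0.0


@dataclass
class ClimateConfig:
    """Synthetic daily temperature / precipitation fields.

    Cell-year anomalies are generated at monthly resolution so that
    sliding-window aggregates carry signal at realistic time scales; daily
    noise rides on top.  Sub-grid standard deviations emulate the 100-m
    within-cell spread of the gridded product.
    """

    temp_window: tuple[int, int] = (32, 90)    # true Feb-Mar temperature window
    precip_window: tuple[int, int] = (75, 135) # true 61-day precipitation window
    temp_monthly_anom_sd: float = 2.4          # deg C
    temp_daily_sd: float = 2.5
    temp_lapse_per_m: float = -0.005
    temp_subgrid_sd: float = 0.45
    precip_mean_mm_day: float = 3.5
    precip_monthly_anom_sd: float = 1.6        # mm/day
    precip_daily_sd: float = 2.0
    precip_subgrid_sd: float = 0.8
    n_days: int = 160                          # daily fields cover days 1..n_days


@dataclass
class WinterConfig:
    """Winter-station series behind the winter-intensity index."""

    temp_mean_c: float = -6.0
    temp_sd_c: float = 1.3
    depth_mean_cm: float = 190.0
    depth_sd_cm: float = 55.0
    temp_depth_corr: float = -0.6  # colder winters tend to be snowier


@dataclass
class ScenarioConfig:
    """Everything the synthetic-data generator needs, with study defaults."""

    n_cells: int = 120
    years: tuple[int, int] = (1999, 2018)
    elevation_range_m: tuple[float, float] = (1500.0, 3100.0)
    regions: tuple[str, ...] = ("EA", "NA", "SA", "WA")
    region_intercepts: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGION_INTERCEPTS))
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COEFFICIENTS))
    sigma_resid_days: float = 9.0
    sigma_year_days: float = 1.9
    n_broods: int = 700
    subgrid_relief_sd_m: float = 80.0   # SD of 200-m sub-cell elevations
    domain_km: float = 100.0            # cells scattered over a square domain
    effort: EffortConfig = field(default_factory=EffortConfig)
    melt: MeltConfig = field(default_factory=MeltConfig)
    climate: ClimateConfig = field(default_factory=ClimateConfig)
    winter: WinterConfig = field(default_factory=WinterConfig)
    detectability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DETECTABILITY))
    precision_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PRECISION_MIX))
    monitoring_cell_fraction: float = 0.04
    #: cap on records one observer files per cell-day (online portals
    #: effectively collapse a visit into one record per species and site);
    #: None removes the cap
    max_records_per_observer_day: int | None = 1
    second_brood_offset_days: float = 30.0
    second_brood_proportion: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        lo, hi = self.elevation_range_m
        if not lo < hi:
            raise ValueError("elevation range must satisfy low < high")
        y0, y1 = self.years
        if y1 < y0:
            raise ValueError("year range is empty")
        for name, p in self.detectability.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"detectability[{name}] outside [0, 1]")
        mix = sum(self.precision_mix.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"precision_mix must sum to 1, got {mix}")
        if not 0.0 <= self.second_brood_proportion <= 1.0:
            raise ValueError("second_brood_proportion outside [0, 1]")
        for r in self.region_intercepts:
            if r not in self.regions:
                raise ValueError(f"intercept for unknown region {r!r}")

    @property
    def year_list(self) -> list[int]:
        return list(range(self.years[0], self.years[1] + 1))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key, sub in (("effort", EffortConfig), ("melt", MeltConfig),
                         ("climate", ClimateConfig), ("winter", WinterConfig)):
            if key in raw and isinstance(raw[key], dict):
                sub_raw = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in raw[key].items()
                }
                raw[key] = sub(**sub_raw)
        for key in ("years", "elevation_range_m", "regions"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)
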