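"""From raw behavioural records to deduplicated broods with dated intervals.

A citizen-science record is a sighting of breeding behaviour (an "atlas
code") on a date in a 1x1 km grid cell.  Known stage durations bound the
offset between observation day and hatch day per code, which turns each
record into an interval of possible hatching dates.  Records of the same
brood overlap in these intervals; a maximum set of pairwise-disjoint
intervals gives the minimum number of distinct broods per cell-year, and one
representative record is kept per disjoint slot.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd
import yaml

from .calendars import APR_1, AUG_31

logger = logging.getLogger(__name__)

__all__ = [
    "StageDurations", "EventKind", "EventInterval", "DedupResult",
    "compute_event_interval", "dedup_broods", "apply_monitoring_precedence",
    "mean_observer_day", "elevation_with_uncertainty",
    "NEST_ELEVATION_SD_M",
]

#: known-nest locations carry a nominal elevation uncertainty of 0.5 m
NEST_ELEVATION_SD_M = 0.5


class EventKind(str, Enum):
    HATCHING = "hatching"
    LAYING = "laying"
    NEST_BUILDING = "nest_building"
    NESTLING = "nestling"


@dataclass(frozen=True)
class StageDurations:
    """Per-atlas-code bounds on (observation day - hatch day).

    ``offsets[code] = (min_offset, max_offset)``; pre-hatch behaviours (nest
    building, incubation) have negative offsets.  ``incubation_days`` and
    ``nestling_days`` shift hatching intervals to laying / nestling events.
    """

    offsets: dict[str, tuple[int, int]]
    nest_building_days: int = 8
    incubation_days: int = 14
    nestling_days: int = 20
    fledgling_days: int = 14

    def __post_init__(self) -> None:
        for code, (lo, hi) in self.offsets.items():
            if lo > hi:
                raise ValueError(f"offsets for {code!r}: min > max")

    @classmethod
    def default(cls) -> "StageDurations":
        ref = importlib.resources.files("snowphen.data") / "stage_durations.yaml"
        with ref.open() as fh:
            raw = yaml.safe_load(fh)
        return cls(offsets={c: (int(v[0]), int(v[1])) for c, v in raw.items()})

    @classmethod
    def from_yaml(cls, path, **durations) -> "StageDurations":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(offsets={c: (int(v[0]), int(v[1])) for c, v in raw.items()},
                   **durations)


@dataclass(frozen=True)
class EventInterval:
    """Earliest / mean / latest possible day-of-year of a breeding event."""

    earliest: float
    latest: float
    kind: EventKind = EventKind.HATCHING
    clamped: bool = False

    def __post_init__(self) -> None:
        if self.earliest > self.latest:
            raise ValueError("interval with earliest > latest")

    @property
    def mean(self) -> float:
        return 0.5 * (self.earliest + self.latest)

    @property
    def width(self) -> float:
        return self.latest - self.earliest

    def shift(self, days: float, kind: EventKind) -> "EventInterval":
        return EventInterval(self.earliest + days, self.latest + days, kind,
                             self.clamped)


def compute_event_interval(obs_day: int, atlas_code: str,
                           stages: StageDurations,
                           kind: EventKind = EventKind.HATCHING,
                           clamp_to_year: bool = True) -> EventInterval:
    """Interval of possible event dates implied by one record.

    The hatching interval is ``[obs_day - max_offset, obs_day - min_offset]``.
    Laying and nest-building intervals shift it back by the incubation (and
    nest-building) duration; the nestling interval is the nest-occupancy
    window ``[earliest hatch, latest hatch + nestling period]``.
    """
    if atlas_code not in stages.offsets:
        raise KeyError(f"atlas code {atlas_code!r} has no stage-duration entry")
    lo_off, hi_off = stages.offsets[atlas_code]
    hatch = EventInterval(obs_day - hi_off, obs_day - lo_off)
    if kind == EventKind.HATCHING:
        out = hatch
    elif kind == EventKind.LAYING:
        out = hatch.shift(-stages.incubation_days, kind)
    elif kind == EventKind.NEST_BUILDING:
        out = hatch.shift(-(stages.incubation_days + stages.nest_building_days),
                          kind)
    elif kind == EventKind.NESTLING:
        out = EventInterval(hatch.earliest,
                            hatch.latest + stages.nestling_days, kind)
    else:  # pragma: no cover - enum is closed
        raise ValueError(kind)
    if clamp_to_year and (out.earliest < 1 or out.latest > 365):
        warnings.warn(
            f"event interval [{out.earliest}, {out.latest}] extends outside "
            "the year; clamping", stacklevel=2)
        out = EventInterval(max(out.earliest, 1), min(out.latest, 365),
                            out.kind, clamped=True)
    return out


# ---------------------------------------------------------------------------
# brood deduplication

@dataclass
class DedupResult:
    """Outcome of per-cell-year brood deduplication."""

    selected_indices: list[int]          # retained records (input positions)
    slot_intervals: list[tuple[float, float]]
    slot_members: list[list[int]]        # inputs pooled into each slot
    extra_same_day: list[int] = field(default_factory=list)

    @property
    def n_broods(self) -> int:
        return len(self.selected_indices)


def _overlap_len(a: tuple[float, float], b: tuple[float, float]) -> float:
    return min(a[1], b[1]) - max(a[0], b[0])


def max_disjoint_intervals(intervals: list[tuple[float, float]]) -> list[int]:
    """Indices of a maximum pairwise-disjoint subset (closed intervals).

    Classical earliest-endpoint greedy; ties broken by earlier start, then
    input position, so the result is deterministic.
    """
    order = sorted(range(len(intervals)),
                   key=lambda i: (intervals[i][1], intervals[i][0], i))
    chosen: list[int] = []
    last_end = -np.inf
    for i in order:
        lo, hi = intervals[i]
        if lo > last_end:  # closed intervals: a shared endpoint overlaps
            chosen.append(i)
            last_end = hi
    return chosen


def dedup_broods(intervals: list[tuple[float, float]],
                 rng: np.random.Generator,
                 observers: list | None = None,
                 obs_days: list | None = None) -> DedupResult:
    """Deduplicate overlapping hatching intervals within one cell-year.

    1. find a maximum set of mutually exclusive intervals (the minimum
       number of distinct broods);
    2. pool every input interval with the selected slot it overlaps (the
       slot of larger overlap when it touches two; ties to the earlier
       slot) and draw one representative per slot uniformly at random;
    3. additionally retain records where a single observer reported more
       than one distinguishable brood on the same day.
    """
    if not intervals:
        return DedupResult([], [], [])
    slots = max_disjoint_intervals(intervals)
    slot_iv = [intervals[i] for i in slots]
    members: list[list[int]] = [[] for _ in slots]
    for i, iv in enumerate(intervals):
        ovs = [(k, _overlap_len(iv, s)) for k, s in enumerate(slot_iv)]
        ovs = [(k, o) for k, o in ovs if o >= 0]  # closed-interval overlap
        if not ovs:  # cannot happen for a maximal selection
            raise RuntimeError("interval overlaps no selected slot")
        best = max(ovs, key=lambda ko: (ko[1], -ko[0]))[0]
        members[best].append(i)
    selected = [m[rng.integers(len(m))] for m in members]

    extra: list[int] = []
    if observers is not None and obs_days is not None:
        groups: dict[tuple, list[int]] = {}
        for i, (o, d) in enumerate(zip(observers, obs_days)):
            groups.setdefault((o, d), []).append(i)
        for g in groups.values():
            if len(g) > 1:
                extra.extend(i for i in g if i not in selected)
    if extra:
        selected = selected + extra
    return DedupResult(selected, slot_iv, members, extra)


def apply_monitoring_precedence(records: pd.DataFrame) -> pd.DataFrame:
    """Drop citizen records in cell-years that have systematic monitoring.

    ``records`` needs columns ``cell_id``, ``year``, ``source`` with source
    values in {'citizen', 'monitoring'}.
    """
    for col in ("cell_id", "year", "source"):
        if col not in records.columns:
            raise KeyError(f"records missing required column {col!r}")
    has_mon = records.loc[records["source"] == "monitoring",
                          ["cell_id", "year"]].drop_duplicates()
    if has_mon.empty:
        return records
    keys = set(map(tuple, has_mon.to_numpy()))
    mask = [
        (src == "monitoring") or ((cell, yr) not in keys)
        for cell, yr, src in zip(records["cell_id"], records["year"],
                                 records["source"])
    ]
    out = records.loc[mask]
    logger.info("monitoring precedence: %d of %d records retained",
                len(out), len(records))
    return out


def mean_observer_day(effort: pd.DataFrame, cell_id, year: int,
                      weighted: bool = True,
                      window: tuple[int, int] = (APR_1, AUG_31)) -> float:
    """Average observer day in a cell-year, person-weighted by default.

    ``effort`` has columns ``cell_id``, ``year``, ``day``, ``n_persons``.
    Only effort between Apr 1 and Aug 31 counts; returns NaN (with a log
    message) when there is none, in which case broods from that cell-year
    are excluded from the models.
    """
    sub = effort[(effort["cell_id"] == cell_id) & (effort["year"] == year)]
    sub = sub[(sub["day"] >= window[0]) & (sub["day"] <= window[1])
              & (sub["n_persons"] > 0)]
    if sub.empty:
        logger.warning("no observer effort in window for cell %s year %d",
                       cell_id, year)
        return float("nan")
    if weighted:
        return float(np.average(sub["day"], weights=sub["n_persons"]))
    return float(sub["day"].mean())


def mean_observer_day_table(effort: pd.DataFrame, weighted: bool = True,
                            window: tuple[int, int] = (APR_1, AUG_31),
                            ) -> pd.DataFrame:
    """Vectorised :func:`mean_observer_day` over all cell-years in a log."""
    sub = effort[(effort["day"] >= window[0]) & (effort["day"] <= window[1])
                 & (effort["n_persons"] > 0)].copy()
    if sub.empty:
        return pd.DataFrame(columns=["cell_id", "year", "observer_day"])
    if weighted:
        sub["wd"] = sub["day"] * sub["n_persons"]
        g = sub.groupby(["cell_id", "year"])
        out = (g["wd"].sum() / g["n_persons"].sum()).rename("observer_day")
    else:
        out = sub.groupby(["cell_id", "year"])["day"].mean().rename(
            "observer_day")
    return out.reset_index()


def elevation_with_uncertainty(precision_class: str, dem_subgrid: np.ndarray,
                               subcell: tuple[int, int] | None = None,
                               point_elevation_m: float | None = None,
                               ) -> tuple[float, float]:
    """Elevation mean and SD of a record given its location precision.

    ``dem_subgrid`` is the cell's 200-m elevation raster (typically 5x5 for
    a 1-km cell).  Known nests get a precise elevation (the reported
    ``point_elevation_m`` when available, otherwise the sub-cell value)
    with a 0.5 m SD; 200-m records get the sub-cell elevation with the SD
    of the 3x3 neighbourhood (clipped at the cell edge); 1-km records get
    the mean and SD over all sub-cells.  Sample SDs (ddof=1) throughout.
    """
    grid = np.asarray(dem_subgrid, dtype=float)
    if grid.ndim != 2 or grid.size == 0 or not np.isfinite(grid).all():
        raise ValueError("DEM sub-grid missing or non-finite")
    if precision_class == "nest":
        if point_elevation_m is not None and np.isfinite(point_elevation_m):
            return float(point_elevation_m), NEST_ELEVATION_SD_M
        if subcell is None:
            raise ValueError("nest-precision record needs a sub-cell index "
                             "or a point elevation")
        return float(grid[subcell]), NEST_ELEVATION_SD_M
    if precision_class == "200m":
        if subcell is None:
            raise ValueError("200m-precision record needs a sub-cell index")
        r, c = subcell
        nb = grid[max(r - 1, 0):r + 2, max(c - 1, 0):c + 2]
        sd = float(np.std(nb, ddof=1)) if nb.size > 1 else 0.0
        return float(grid[r, c]), sd
    if precision_class == "1km":
        return float(grid.mean()), float(np.std(grid, ddof=1))
    raise ValueError(f"unknown precision class {precision_class!r}")
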