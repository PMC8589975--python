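"""From behavioural records to deduplicated broods with hatching intervals.

Generates a small citizen-science dataset, shows how a single atlas-code
record becomes an interval of possible hatching dates, and runs the
monitoring-precedence + deduplication chain that turns overlapping records
into a minimum set of distinct broods.
"""

from snowphen.config import ScenarioConfig
from snowphen.pipeline import prepare_broods
from snowphen.records import StageDurations, compute_event_interval
from snowphen.synth import simulate

stages = StageDurations.default()
iv = compute_event_interval(180, "food_for_young", stages)
print(f"record 'food for young' on day 180 -> hatching interval "
      f"[{iv.earliest:.0f}, {iv.latest:.0f}], mean {iv.mean:.0f}, "
      f"width {iv.width:.0f} d")
# The width quantifies dating uncertainty: the chick-feeding stage lasts
# ~20 days, so the hatch day is known only to within that window.

ds = simulate(ScenarioConfig(n_cells=60, years=(2009, 2018), n_broods=250,
                             seed=1))
broods, counts = prepare_broods(ds.records, ds.effort, ds.landscape.cells,
                                ds.landscape.subgrids, seed=1)
print(f"\n{counts['input']} raw records")
print(f"{counts['after_precedence']} after monitoring precedence")
print(f"{counts['after_dedup']} distinct broods after deduplication")
print(f"mean interval width {broods.hatch_width.mean():.1f} d "
      f"(0 = exact monitoring records)")
# Each retained brood carries its hatching interval, elevation mean/SD by
# location precision, and the cell-year's person-weighted mean observer day.
print(broods[["cell_id", "year", "hatch_mean", "hatch_width",
              "elevation_mean", "elevation_sd", "observer_day"]].head())
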