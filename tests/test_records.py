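"""Interval arithmetic, deduplication and covariate extraction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snowphen.records import (EventKind, StageDurations,
                              apply_monitoring_precedence,
                              compute_event_interval, dedup_broods,
                              elevation_with_uncertainty,
                              max_disjoint_intervals, mean_observer_day)


@pytest.fixture(scope="module")
def stages():
    return StageDurations.default()


class TestEventInterval:
    @pytest.mark.parametrize("code,day,expected", [
        ("hatch", 170, (170, 170, 170)),          # direct hatch observation
        ("food_for_young", 180, (160, 170, 180)),  # offsets (0, 20)
        ("nest_building", 150, (164, 168, 172)),   # offsets (-22, -14)
        ("incubation", 140, (140, 147, 154)),      # offsets (-14, 0)
    ])
    def test_hatching_interval_formula(self, stages, code, day, expected):
        iv = compute_event_interval(day, code, stages)
        assert (iv.earliest, iv.mean, iv.latest) == expected

    def test_laying_shifts_back_by_incubation(self, stages):
        h = compute_event_interval(180, "food_for_young", stages)
        lay = compute_event_interval(180, "food_for_young", stages,
                                     EventKind.LAYING)
        assert lay.earliest == h.earliest - stages.incubation_days
        assert lay.latest == h.latest - stages.incubation_days

    def test_nestling_is_occupancy_window(self, stages):
        h = compute_event_interval(180, "food_for_young", stages)
        nest = compute_event_interval(180, "food_for_young", stages,
                                      EventKind.NESTLING)
        assert nest.earliest == h.earliest
        assert nest.latest == h.latest + stages.nestling_days

    def test_unknown_code_raises(self, stages):
        with pytest.raises(KeyError, match="no stage-duration entry"):
            compute_event_interval(100, "soaring", stages)

    def test_interval_outside_year_is_clamped_with_warning(self, stages):
        with pytest.warns(UserWarning, match="clamping"):
            iv = compute_event_interval(10, "food_for_young", stages)
        assert iv.earliest == 1 and iv.clamped

    @given(st.integers(min_value=60, max_value=250),
           st.integers(min_value=-30, max_value=30))
    @settings(max_examples=50, deadline=None)
    def test_translation_equivariance(self, day, k):
        stages = StageDurations.default()
        a = compute_event_interval(day, "food_for_young", stages,
                                   clamp_to_year=False)
        b = compute_event_interval(day + k, "food_for_young", stages,
                                   clamp_to_year=False)
        assert b.earliest == a.earliest + k and b.latest == a.latest + k


def brute_force_max_disjoint(intervals):
    """Exhaustive maximum pairwise-disjoint subset size (closed overlap)."""
    n = len(intervals)
    conflict = [0] * n
    for i in range(n):
        for j in range(n):
            if i != j and (min(intervals[i][1], intervals[j][1])
                           >= max(intervals[i][0], intervals[j][0])):
                conflict[i] |= 1 << j
    best = 0
    for s in range(1 << n):
        ok = True
        m = s
        while m:
            i = (m & -m).bit_length() - 1
            if s & conflict[i]:
                ok = False
                break
            m &= m - 1
        if ok:
            best = max(best, bin(s).count("1"))
    return best


class TestDedup:
    def test_disjoint_inputs_all_retained(self):
        res = dedup_broods([(1, 10), (20, 30)], np.random.default_rng(0))
        assert res.n_broods == 2

    def test_nested_intervals_oracle(self):
        # max disjoint subset is {[5,10], [15,20]}
        res = dedup_broods([(1, 30), (5, 10), (15, 20)],
                           np.random.default_rng(0))
        assert res.n_broods == 2

    def test_shared_endpoint_counts_as_overlap(self):
        res = dedup_broods([(1, 10), (10, 20)], np.random.default_rng(0))
        assert res.n_broods == 1

    def test_representative_drawn_uniformly(self):
        rng = np.random.default_rng(42)
        counts = {0: 0, 1: 0}
        n = 4000
        for _ in range(n):
            res = dedup_broods([(1, 10), (5, 15), (20, 30)], rng)
            first = [i for i in res.selected_indices if i in (0, 1)][0]
            counts[first] += 1
        frac = counts[0] / n
        assert abs(frac - 0.5) < 0.025

    def test_matches_exhaustive_oracle_on_random_instances(self):
        rng = np.random.default_rng(1)
        for _ in range(150):
            n = rng.integers(1, 11)
            lo = rng.integers(1, 60, n)
            iv = [(int(a), int(a + rng.integers(0, 25))) for a in lo]
            res = dedup_broods(iv, rng)
            assert res.n_broods == brute_force_max_disjoint(iv)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(5)
        iv = [(1, 12), (4, 9), (15, 22), (18, 30), (40, 45)]
        first = dedup_broods(iv, rng)
        selected = [iv[i] for i in first.selected_indices]
        second = dedup_broods(selected, rng)
        assert sorted(second.slot_intervals) == sorted(selected)
        assert second.n_broods == first.n_broods

    def test_same_observer_same_day_broods_kept(self):
        # one observer reports two distinguishable broods on one day
        res = dedup_broods([(100, 120), (105, 125)],
                           np.random.default_rng(0),
                           observers=["a", "a"], obs_days=[110, 110])
        assert res.n_broods == 2

    def test_empty_input(self):
        assert dedup_broods([], np.random.default_rng(0)).n_broods == 0

    @given(st.lists(st.tuples(st.integers(0, 50), st.integers(0, 30)),
                    min_size=1, max_size=9),
           st.integers(-20, 20))
    @settings(max_examples=60, deadline=None)
    def test_shift_invariance_of_count(self, raw, k):
        iv = [(a, a + w) for a, w in raw]
        shifted = [(a + k, b + k) for a, b in iv]
        assert (len(max_disjoint_intervals(iv))
                == len(max_disjoint_intervals(shifted)))


class TestMonitoringPrecedence:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["cell_id", "year", "source"])

    def test_citizen_dropped_where_monitoring_exists(self):
        df = self.make([(1, 2000, "citizen")] * 3 + [(1, 2000, "monitoring")])
        assert len(apply_monitoring_precedence(df)) == 1

    def test_citizen_only_cell_year_unchanged(self):
        df = self.make([(1, 2000, "citizen"), (2, 2000, "citizen")])
        assert len(apply_monitoring_precedence(df)) == 2

    def test_only_monitored_cell_years_filtered(self):
        rng = np.random.default_rng(0)
        rows = []
        mon = {(c, 2000) for c in range(4)}
        for c in range(10):
            rows += [(c, 2000, "citizen")] * int(rng.integers(1, 4))
            if (c, 2000) in mon:
                rows.append((c, 2000, "monitoring"))
        out = apply_monitoring_precedence(self.make(rows))
        kept_citizen = out[out.source == "citizen"]
        assert set(kept_citizen.cell_id) == set(range(4, 10))
        assert (out[out.source == "monitoring"].cell_id.tolist()
                == sorted(c for c, _ in mon))


class TestObserverDay:
    def make(self, rows):
        return pd.DataFrame(rows,
                            columns=["cell_id", "year", "day", "n_persons"])

    def test_single_person(self):
        eff = self.make([(1, 2000, 100, 1)])
        assert mean_observer_day(eff, 1, 2000) == 100

    def test_person_weighted_mean(self):
        eff = self.make([(1, 2000, 100, 2), (1, 2000, 130, 1)])
        assert mean_observer_day(eff, 1, 2000) == pytest.approx(110.0)

    def test_plain_mean_option(self):
        eff = self.make([(1, 2000, 100, 2), (1, 2000, 130, 1)])
        assert mean_observer_day(eff, 1, 2000,
                                 weighted=False) == pytest.approx(115.0)

    def test_effort_outside_window_is_missing(self):
        eff = self.make([(1, 2000, 70, 5)])   # March only
        assert np.isnan(mean_observer_day(eff, 1, 2000))


class TestElevationUncertainty:
    def test_nest_class_sd_half_metre(self):
        grid = np.full((5, 5), 2400.0)
        mean, sd = elevation_with_uncertainty("nest", grid, (2, 2))
        assert sd == 0.5

    def test_nest_class_uses_point_elevation_when_given(self):
        grid = np.full((5, 5), 2400.0)
        mean, sd = elevation_with_uncertainty("nest", grid, (2, 2), 2417.3)
        assert mean == 2417.3 and sd == 0.5

    def test_flat_neighbourhood_sd_zero(self):
        grid = np.full((5, 5), 2400.0)
        mean, sd = elevation_with_uncertainty("200m", grid, (2, 2))
        assert sd == 0.0 and mean == 2400.0

    def test_km_cell_arithmetic(self):
        vals = np.arange(2000.0, 2500.0, 20.0).reshape(5, 5)
        mean, sd = elevation_with_uncertainty("1km", vals)
        assert mean == pytest.approx(vals.mean())
        assert sd == pytest.approx(np.std(vals, ddof=1))

    def test_edge_subcell_neighbourhood_clipped(self):
        grid = np.arange(25.0).reshape(5, 5)
        mean, sd = elevation_with_uncertainty("200m", grid, (0, 0))
        nb = grid[0:2, 0:2]
        assert sd == pytest.approx(np.std(nb, ddof=1))

    def test_unknown_class_raises(self):
        with pytest.raises(ValueError, match="precision class"):
            elevation_with_uncertainty("10km", np.ones((5, 5)))
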