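"""The synthetic study system: determinism, ground truth, calibration."""

import numpy as np
import pandas as pd
import pytest

from snowphen.config import ScenarioConfig
from snowphen.environment import snowmelt_metrics, winter_intensity
from snowphen.synth import (generate_broods, generate_climate,
                            generate_landscape, generate_observations,
                            generate_snow_series, generate_winter_series,
                            simulate)
from conftest import small_config


class TestLandscape:
    def test_cell_sd_equals_subgrid_sample_sd(self):
        land = generate_landscape(small_config())
        for cid, grid in list(land.subgrids.items())[:10]:
            row = land.cells[land.cells.cell_id == cid].iloc[0]
            assert row.elev_mean == pytest.approx(grid.mean())
            assert row.elev_sd == pytest.approx(np.std(grid, ddof=1))

    def test_flat_landscape_zero_sd(self):
        cfg = small_config(subgrid_relief_sd_m=0.0)
        land = generate_landscape(cfg)
        np.testing.assert_allclose(land.cells.elev_sd, 0.0, atol=1e-9)

    def test_deterministic_given_seed(self):
        a = generate_landscape(small_config(seed=3))
        b = generate_landscape(small_config(seed=3))
        pd.testing.assert_frame_equal(a.cells, b.cells)

    def test_nonpositive_cells_rejected(self):
        with pytest.raises(ValueError, match="n_cells"):
            ScenarioConfig(n_cells=0)

    def test_all_regions_present(self):
        land = generate_landscape(small_config())
        assert set(land.cells.region) == {"EA", "NA", "SA", "WA"}


class TestSnow:
    def test_melt_onset_shifts_later_with_elevation(self):
        cfg = ScenarioConfig(n_cells=150, years=(2005, 2005), seed=4)
        land = generate_landscape(cfg)
        allseries = generate_snow_series(land, cfg)
        elev = land.cells.elev_mean.to_numpy()
        onset = np.array([s.true_meltstart for s in allseries])
        assert np.corrcoef(elev, onset)[0, 1] > 0.3

    def test_downstream_metrics_recover_stored_truth(self):
        cfg = small_config(n_cells=30)
        land = generate_landscape(cfg)
        for s in generate_snow_series(land, cfg):
            m = snowmelt_metrics(s)
            assert (m.meltstart, m.meltend) == (s.true_meltstart,
                                                s.true_meltend)

    def test_empty_year_range_rejected(self):
        with pytest.raises(ValueError):
            small_config(years=(2010, 2005))


def _windex(cfg):
    st = generate_winter_series(cfg)
    return winter_intensity(st.year, st.mean_temp, st.mean_snow_depth)


class TestBroods:
    def _env(self, cfg):
        land = generate_landscape(cfg)
        snow = generate_snow_series(land, cfg)
        climate = generate_climate(land, cfg)
        return land, snow, climate, _windex(cfg)

    def test_all_zero_coefficients_give_region_intercepts(self):
        cfg = small_config(sigma_resid_days=0.0, sigma_year_days=0.0)
        cfg.true_coefficients = {k: 0.0 for k in cfg.true_coefficients}
        land, snow, climate, wi = self._env(cfg)
        truth = generate_broods(land, climate, snow, wi, cfg)
        b = truth.broods
        for region, intercept in cfg.region_intercepts.items():
            sel = b[b.region == region]
            if len(sel):
                np.testing.assert_allclose(sel.true_hatch, intercept)

    def test_pure_elevation_effect_is_affine(self):
        cfg = small_config(sigma_resid_days=0.0, sigma_year_days=0.0)
        cfg.true_coefficients = {k: 0.0 for k in cfg.true_coefficients}
        cfg.true_coefficients["elevation"] = 3.0
        cfg.region_intercepts = {r: 175.0 for r in cfg.regions}
        land, snow, climate, wi = self._env(cfg)
        truth = generate_broods(land, climate, snow, wi, cfg)
        b = truth.broods
        np.testing.assert_allclose(b.true_hatch,
                                   175.0 + 3.0 * b.z_elevation, atol=1e-9)

    def test_moments_match_linear_predictor(self):
        # law of large numbers: with all noise off except the residual,
        # mean(hatch) ~= mean(region intercept) + beta . mean(z) and the
        # residual variance adds to the linear predictor's variance
        cfg = small_config(n_broods=8000, sigma_year_days=0.0)
        land, snow, climate, wi = self._env(cfg)
        truth = generate_broods(land, climate, snow, wi, cfg)
        b = truth.broods
        beta = cfg.true_coefficients
        zcols = {
            "elevation": b.z_elevation, "elevation2": b.z_elevation ** 2,
            "year": b.z_year, "elevation_year": b.z_elevation * b.z_year,
            "winter": b.z_winter, "precipitation": b.z_precipitation,
            "meltstart": b.z_meltstart, "temperature": b.z_temperature,
        }
        lin = np.array([cfg.region_intercepts[r] for r in b.region])
        for k, z in zcols.items():
            lin = lin + beta[k] * np.asarray(z)
        resid = b.true_hatch - lin
        se_mean = cfg.sigma_resid_days / np.sqrt(len(b))
        assert abs(resid.mean()) < 3 * se_mean
        sd = np.std(resid, ddof=1)
        se_sd = cfg.sigma_resid_days / np.sqrt(2 * (len(b) - 1))
        assert abs(sd - cfg.sigma_resid_days) < 3 * se_sd

    def test_missing_coefficient_rejected(self):
        cfg = small_config()
        del cfg.true_coefficients["meltstart"]
        land, snow, climate, wi = self._env(cfg)
        with pytest.raises(ValueError, match="meltstart"):
            generate_broods(land, climate, snow, wi, cfg)

    def test_second_brood_mixture_shifts_later(self):
        cfg = small_config(second_brood_proportion=0.5,
                           second_brood_offset_days=30.0, n_broods=2000)
        land, snow, climate, wi = self._env(cfg)
        truth = generate_broods(land, climate, snow, wi, cfg)
        b = truth.broods
        gap = (b[b.second_brood].true_hatch.mean()
               - b[~b.second_brood].true_hatch.mean())
        assert 25 < gap < 35


class TestObservations:
    def test_zero_detectability_means_no_citizen_records(self):
        cfg = small_config(monitoring_cell_fraction=0.0)
        cfg.detectability = {k: 0.0 for k in cfg.detectability}
        ds = simulate(cfg)
        assert len(ds.records) == 0

    def test_empty_detectability_rejected(self):
        cfg = small_config()
        cfg.detectability = {}
        with pytest.raises(ValueError, match="detectability"):
            simulate(cfg)

    def test_every_record_joins_back_to_truth(self, dataset):
        truth_ids = set(dataset.truth.broods.brood_id)
        assert set(dataset.records.brood_id) <= truth_ids

    def test_atlas_code_matches_active_stage(self, dataset):
        m = dataset.records.merge(dataset.truth.broods, on="brood_id")
        cit = m[m.source == "citizen"]
        off = cit.day - cit.true_hatch
        bounds = {"nest_building": (-22, -14), "incubation": (-14, 0),
                  "food_for_young": (0, 20), "fledglings": (20, 34)}
        for code, (lo, hi) in bounds.items():
            sub = off[cit.atlas_code == code]
            assert ((sub >= lo) & (sub <= hi)).all()

    def test_full_determinism_under_fixed_seed(self):
        a = simulate(small_config(seed=19, n_cells=20, n_broods=60))
        b = simulate(small_config(seed=19, n_cells=20, n_broods=60))
        pd.testing.assert_frame_equal(a.records, b.records)
        pd.testing.assert_frame_equal(a.effort, b.effort)
        pd.testing.assert_frame_equal(a.truth.broods, b.truth.broods)

    def test_intervals_contain_true_hatch(self, dataset, prepared):
        # back-computed hatching intervals must contain the generator's
        # true hatch day for (nearly) all broods; monitoring records can
        # miss by sub-day rounding only
        broods, _ = prepared
        m = broods.merge(dataset.truth.broods[["brood_id", "true_hatch"]],
                         on="brood_id")
        inside = ((m.true_hatch >= m.hatch_lo - 0.5)
                  & (m.true_hatch <= m.hatch_hi + 0.5))
        assert inside.mean() >= 0.95
        cit = m[m.source == "citizen"]
        strict = ((cit.true_hatch >= cit.hatch_lo)
                  & (cit.true_hatch <= cit.hatch_hi))
        assert strict.all()


class TestConfig:
    def test_precision_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="precision_mix"):
            ScenarioConfig(precision_mix={"nest": 0.5, "1km": 0.4})

    def test_yaml_round_trip(self, tmp_path):
        cfg = small_config(n_broods=99)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        back = ScenarioConfig.from_yaml(path)
        assert back.n_broods == 99
        assert back.years == cfg.years
        assert back.melt.duration_mean_days == cfg.melt.duration_mean_days
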