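"""Shared fixtures: one small synthetic scenario reused across the suite."""

import logging

import pytest

from snowphen.config import ScenarioConfig
from snowphen.pipeline import environment_stage, prepare_broods
from snowphen.synth import simulate

logging.getLogger("snowphen").setLevel(logging.ERROR)


def small_config(seed: int = 7, **overrides) -> ScenarioConfig:
    defaults = dict(n_cells=60, years=(2009, 2018), n_broods=250, seed=seed)
    defaults.update(overrides)
    return ScenarioConfig(**defaults)


@pytest.fixture(scope="session")
def dataset():
    """A reduced synthetic dataset (60 cells, 10 years, 250 true broods)."""
    return simulate(small_config())


@pytest.fixture(scope="session")
def prepared(dataset):
    broods, counts = prepare_broods(
        dataset.records, dataset.effort, dataset.landscape.cells,
        dataset.landscape.subgrids, seed=3)
    broods = broods.dropna(subset=["observer_day"]).reset_index(drop=True)
    return broods, counts


@pytest.fixture(scope="session")
def enriched(dataset, prepared):
    broods, _ = prepared
    return environment_stage(dataset, broods, use_true_windows=True)
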