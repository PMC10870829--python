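import numpy as np
import pandas as pd
import pytest

from coalburden.config import PipelineConfig, WorldConfig
from coalburden.dispersion import compute_raw_exposure
from coalburden.synthetic_world import generate_world


def small_world_config(**overrides) -> WorldConfig:
    """A tiny world for fast unit tests."""
    base = dict(n_egus=4, n_years=5, grid_size=8, person_years_mean=800.0,
                n_parcels=60, releases_per_year=2, seed=7)
    base.update(overrides)
    return WorldConfig(**base)


@pytest.fixture(scope="session")
def small_config():
    return small_world_config()


@pytest.fixture(scope="session")
def small_world(small_config):
    return generate_world(small_config)


@pytest.fixture(scope="session")
def small_raw(small_world, small_config):
    return compute_raw_exposure(small_world["inventory"], small_config)


@pytest.fixture(scope="session")
def default_config():
    """The default study conditions: 400 zips x 12 years x 4 strata."""
    return WorldConfig()


@pytest.fixture(scope="session")
def default_world(default_config):
    return generate_world(default_config)


@pytest.fixture(scope="session")
def pipeline_run(tmp_path_factory):
    """One full default pipeline run, shared by tests that audit its outputs."""
    from coalburden.pipeline import run

    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig()
    manifest = run(cfg, outdir, stages=("all",), seed=1)
    return {"outdir": outdir, "config": cfg, "manifest": manifest}


def two_cell_panel(deaths0=100, deaths1=121, py=1000.0):
    """Single-stratum two-zip panel with exposure 0 vs 1 (closed-form MLE)."""
    panel = pd.DataFrame({
        "zip_id": [0, 1], "year": [2000, 2000], "stratum_id": ["all", "all"],
        "person_years": [py, py], "deaths": [deaths0, deaths1]})
    exposure = pd.DataFrame({"zip_id": [0, 1], "year": [2000, 2000],
                             "coal_pm25": [0.0, 1.0]})
    return panel, exposure
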