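import numpy as np
import pytest

from stilquant.pipeline import score_tile
from stilquant.simtiles import TileSimConfig, render_tile


def small_tile_config(**overrides) -> TileSimConfig:
    """A fast 256x256 tile with the default ring-of-nests layout."""
    kw = dict(height=256, width=256, tumor_nest_count=4, nest_radius=(22.0, 32.0))
    kw.update(overrides)
    return TileSimConfig(**kw)


@pytest.fixture(scope="session")
def tile_and_truth():
    """One 256x256 tile with a 25% true sTIL and its ground truth."""
    return render_tile(small_tile_config(target_stil_percent=25.0), seed=11)


@pytest.fixture(scope="session")
def scored_tile(tile_and_truth):
    tile, gt = tile_and_truth
    return score_tile(tile, tumor_mask=gt.tumor_region, tumor_mask_source="ground_truth", seed=11)


@pytest.fixture(scope="session")
def cohort():
    from stilquant.simcohort import simulate_cohort

    return simulate_cohort(seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
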