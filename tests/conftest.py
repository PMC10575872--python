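import datetime as dt

import numpy as np
import pytest

from swirmap import Scene, SiteTruthConfig, generate_truth


@pytest.fixture
def small_config():
    """A tiny noise-free site: deterministic and fast."""
    return SiteTruthConfig(
        grid_rows=30,
        grid_cols=30,
        year_start=2001,
        year_end=2010,
        sd_wet=0.0,
        sd_dry=0.0,
        seed=11,
    )


@pytest.fixture
def small_truth(small_config):
    return generate_truth(small_config)


def make_scene(swir, qa=None, date=dt.date(2005, 7, 15), scene_id="s0"):
    """Hand-built scene helper for compositing tests."""
    swir = None if swir is None else np.asarray(swir, dtype=float)
    if qa is None:
        shape = swir.shape if swir is not None else (2, 2)
        qa = np.zeros(shape, dtype=np.uint8)
    return Scene(date=date, scene_id=scene_id, qa=np.asarray(qa), swir=swir)
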