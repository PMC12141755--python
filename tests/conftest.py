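import numpy as np
import pandas as pd
import pytest

import photobackcast as pb
from photobackcast import synthetic_data as sd


@pytest.fixture(scope="session")
def scheme():
    return pb.default_scheme()


@pytest.fixture(scope="session")
def fine_scheme():
    """A finer legend whose conifer density classes merge to one class."""
    fine = (
        (1, "dense conifer"),
        (2, "moderate conifer"),
        (3, "open conifer"),
        (4, "herbaceous"),
        (5, "wetland"),
    )
    coarse = ((1, "coniferous forest"), (4, "herbaceous"), (5, "wetland"))
    merge = {1: 1, 2: 1, 3: 1, 4: 4, 5: 5}
    return pb.LandCoverScheme(fine, merge_map=merge, merged_categories=coarse)


@pytest.fixture(scope="session")
def small_world(scheme):
    """A compact synthetic landscape + survey sites shared across tests."""
    raster = sd.generate_landscape(
        scheme, (160, 160), sd.DEFAULT_COMPOSITION, sd.DEFAULT_AUTOCORR_CELLS, seed=11
    )
    sites = sd.random_sites(raster, 120, seed=12, margin_m=500.0)
    return raster, sites


def uniform_image(label: int, shape=(10, 10)):
    return pb.ClassifiedImage(
        np.full(shape, label, dtype=np.uint8), np.ones(shape, dtype=bool)
    )
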