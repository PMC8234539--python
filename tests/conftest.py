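import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from radsurv import synthdata


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_survival(rng, n, censor_frac=0.3):
    """Random censored survival data with at least one event."""
    time = rng.uniform(1.0, 50.0, size=n)
    event = (rng.uniform(size=n) >= censor_frac).astype(int)
    if event.sum() == 0:
        event[0] = 1
    return time, event


@pytest.fixture(scope="session")
def small_cohort():
    """A small image cohort shared across tests (generation is cheap)."""
    cfg = synthdata.CohortConfig(
        n_patients=40, grid_shape=(16, 16, 16),
        lesion_radius_range=(3.0, 6.0), seed=7,
    )
    return synthdata.generate_cohort(cfg)


@pytest.fixture(scope="session")
def toy_roi():
    from radsurv.radiomics import ImageROI

    r = np.random.default_rng(3)
    img = r.normal(10, 2, size=(12, 12, 12))
    mask = np.zeros((12, 12, 12), dtype=bool)
    mask[3:9, 3:9, 3:9] = True
    return ImageROI(img, mask, (1.0, 1.0, 1.0))
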