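import numpy as np
import pytest

from histocode.synthetic import CohortParams, generate_cohort
from histocode.tiling import TilingParams


@pytest.fixture(scope="session")
def tiny_params() -> CohortParams:
    """Small, fast cohort for unit tests (32-px tiles, 6 patients)."""
    return CohortParams(
        n_patients=6, slides_per_patient=(2, 2), grid_side=6, tile_size=32, seed=7
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_params):
    return generate_cohort(tiny_params)


@pytest.fixture(scope="session")
def tiny_tiling(tiny_params) -> TilingParams:
    return TilingParams(tile_size=tiny_params.tile_size)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
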