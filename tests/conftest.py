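import numpy as np
import pandas as pd
import pytest

from densiscale.data_io import compute_density_matrix
from densiscale.synthetic import IndicatorSpec, SyntheticSpec, simulate


def single_indicator_spec(seed: int, model: str = "segmented", noise_sd: float = 0.15,
                          rho: float = 0.0, **law) -> SyntheticSpec:
    """One-indicator study spec used by the scaling recovery tests."""
    defaults = dict(y0=0.05, beta_L=0.8, beta_H=1.4, d_star=27.0)
    if model == "single":
        defaults = dict(y0=0.05, beta_L=1.0)
    defaults.update(law)
    return SyntheticSpec(
        n_regions=348,
        indicators=[IndicatorSpec("x", model, **defaults)],
        residual_blocks=[["x"]],
        rho_block=rho,
        noise_sd=noise_sd,
        seed=seed,
    )


def three_block_spec(seed: int, rho: float = 0.6, noise_sd: float = 0.15) -> SyntheticSpec:
    """Default 12-indicator, 3-block study spec (the planted network truth)."""
    return SyntheticSpec(seed=seed, rho_block=rho, noise_sd=noise_sd)


@pytest.fixture(scope="session")
def default_table():
    return simulate(SyntheticSpec(seed=11))


@pytest.fixture(scope="session")
def default_dm(default_table):
    return compute_density_matrix(default_table)


@pytest.fixture(scope="session")
def small_table_csv(tmp_path_factory):
    """Tiny 3-region, 2-indicator region table on disk."""
    path = tmp_path_factory.mktemp("io") / "regions.csv"
    pd.DataFrame(
        {
            "region_id": ["A", "B", "C"],
            "area": [100.0, 200.0, 50.0],
            "population": [2700, 1000, 4000],
            "crime": [30, 12, 99],
            "deaths": [5, 0, 21],
        }
    ).to_csv(path, index=False)
    return path


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
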